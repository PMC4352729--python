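# TCGA LUSC sample IDs with all four omics layers (transcribed list of 129)
TCGA-18-3414
TCGA-33-4566
TCGA-66-2795
TCGA-39-5021
TCGA-39-5037
TCGA-18-3411
TCGA-60-2713
TCGA-66-2744
TCGA-51-4080
TCGA-37-4141
TCGA-18-3410
TCGA-18-3417
TCGA-66-2742
TCGA-21-1075
TCGA-33-4547
TCGA-18-3412
TCGA-66-2786
TCGA-66-2771
TCGA-39-5031
TCGA-33-4582
TCGA-22-0944
TCGA-33-4583
TCGA-66-2787
TCGA-21-1077
TCGA-34-5240
TCGA-46-3766
TCGA-66-2785
TCGA-46-3767
TCGA-37-4135
TCGA-66-2791
TCGA-18-3406
TCGA-66-2780
TCGA-66-2754
TCGA-21-1072
TCGA-66-2789
TCGA-22-4604
TCGA-66-2781
TCGA-18-3415
TCGA-37-4133
TCGA-66-2788
TCGA-60-2706
TCGA-18-4721
TCGA-18-3419
TCGA-33-4533
TCGA-66-2792
TCGA-60-2696
TCGA-22-4613
TCGA-46-3765
TCGA-33-4538
TCGA-22-4607
TCGA-60-2710
TCGA-22-4601
TCGA-18-3421
TCGA-37-4130
TCGA-22-4596
TCGA-60-2698
TCGA-66-2782
TCGA-18-3408
TCGA-66-2790
TCGA-33-4532
TCGA-60-2711
TCGA-43-3920
TCGA-18-3416
TCGA-66-2737
TCGA-22-4595
TCGA-60-2712
TCGA-46-3769
TCGA-66-2793
TCGA-66-2753
TCGA-22-4591
TCGA-60-2708
TCGA-43-3394
TCGA-66-2783
TCGA-66-2734
TCGA-22-4594
TCGA-66-2758
TCGA-51-4079
TCGA-66-2794
TCGA-34-2596
TCGA-37-3789
TCGA-60-2722
TCGA-37-3792
TCGA-66-2800
TCGA-34-2608
TCGA-46-3768
TCGA-60-2721
TCGA-39-5039
TCGA-56-1622
TCGA-43-2581
TCGA-43-2578
TCGA-60-2724
TCGA-63-5131
TCGA-60-2725
TCGA-60-2695
TCGA-66-2727
TCGA-60-2716
TCGA-39-5036
TCGA-51-4081
TCGA-34-2600
TCGA-39-5011
TCGA-66-2759
TCGA-39-5034
TCGA-22-1012
TCGA-66-2766
TCGA-34-5241
TCGA-60-2723
TCGA-63-5128
TCGA-22-1011
TCGA-66-2767
TCGA-39-5029
TCGA-66-2755
TCGA-39-5035
TCGA-21-1079
TCGA-66-2770
TCGA-39-5028
TCGA-60-2719
TCGA-39-5030
TCGA-21-1078
TCGA-66-2765
TCGA-18-3407
TCGA-60-2720
TCGA-66-2768
TCGA-21-1080
TCGA-66-2763
TCGA-18-4086
TCGA-60-2714
TCGA-33-4586
TCGA-21-1076
TCGA-66-2777
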
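import numpy as np
import pandas as pd
import pytest

from omicsnet.io_formats import MultiOmicsDataset, OmicsLayer


def make_dataset(mrna=None, mirna=None, methylation=None, cnv=None,
                 samples=None):
    """Build a small aligned dataset from {feature: per-sample values} dicts;
    layers left unspecified get one constant pad feature."""
    source = mrna or mirna or methylation or cnv
    n = len(np.asarray(next(iter(source.values()))))
    samples = samples or [f"S{i:03d}" for i in range(n)]

    def layer(tag, d, fill):
        if not d:
            d = {f"{tag}_pad": np.full(n, fill)}
        arr = np.vstack([np.asarray(v, dtype=float) for v in d.values()])
        return OmicsLayer(tag, pd.DataFrame(arr, index=list(d.keys()),
                                            columns=samples))

    return MultiOmicsDataset(
        mrna=layer("mrna", mrna, 0.0),
        mirna=layer("mirna", mirna, 0.0),
        methylation=layer("methylation", methylation, 0.5),
        cnv=layer("cnv", cnv, 0.0),
        sample_ids=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
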
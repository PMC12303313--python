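import numpy as np
import pandas as pd
import pytest

from phycomet import FeatureTable, PhenoData


def make_feature_table(mz_med, rt_med, intensities: dict[str, list[float]],
                       mz_halfwidth_ppm=10.0, rt_halfwidth=15.0) -> FeatureTable:
    """Small feature table builder with symmetric envelopes."""
    mz = np.asarray(mz_med, dtype=float)
    rt = np.asarray(rt_med, dtype=float)
    n = mz.size
    features = pd.DataFrame(
        {
            "mz_min": mz * (1 - mz_halfwidth_ppm * 1e-6),
            "mz_med": mz,
            "mz_max": mz * (1 + mz_halfwidth_ppm * 1e-6),
            "rt_min": rt - rt_halfwidth,
            "rt_med": rt,
            "rt_max": rt + rt_halfwidth,
        },
        index=pd.Index([f"F{i + 1}" for i in range(n)], name="feature_id"),
    )
    inten = pd.DataFrame(intensities, index=features.index, dtype=float)
    return FeatureTable(features, inten)


def make_pheno(rows) -> PhenoData:
    """rows: iterable of (sample_id, species, compartment, culture, polarity, replicate)."""
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "species", "compartment", "culture", "polarity", "replicate"],
    )
    return PhenoData(df.set_index("sample_id"))


@pytest.fixture
def mono_co_pheno():
    """One species/compartment/polarity: 8 mono + 4 co replicates."""
    rows = [(f"mono{r}", "SM", "exo", "mono", "pos", r) for r in range(1, 9)]
    rows += [(f"co{r}", "SM", "exo", "co", "pos", r) for r in range(1, 5)]
    return make_pheno(rows)
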
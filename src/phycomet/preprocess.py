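"""Feature-table transformation and presence/absence construction.

The raw intensity matrix is log-transformed (base 2 by default; zeros stay 0
as the missing-value code), a single intensity cutoff is fitted per dataset as
the lower q-tail of a normal distribution over all positive transformed
intensities, and thresholding yields a binary presence/absence matrix used by
the chemodiversity and exchange analyses.  A separate operation builds
combined mono-culture pseudo-replicates (pair sums of the 8 mono replicates)
so mono- and 4-replicate co-culture conditions become comparable in PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .tables_io import FeatureTable, PhenoData


@dataclass
class PresenceMatrix:
    """Binary feature x sample matrix with the cutoff that produced it."""

    matrix: pd.DataFrame  # entries in {0, 1}
    cutoff: float
    cutoff_method: str = "normal lower-tail on pooled positive log-intensities"
    q: float = 0.05

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("presence matrix entries must be 0/1")
        if not np.isfinite(self.cutoff):
            raise ValidationError("cutoff must be finite")


def log_transform(table: FeatureTable, base: float = 2.0) -> FeatureTable:
    """Log-transform positive intensities; zeros remain 0 (missing code).

    Raw intensities in (0, 1) would transform negative; they are floored to 0
    with a warning so that 0 keeps its missing-value semantics.
    """
    vals = table.intensities.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValidationError("negative intensity in input")
    out = np.zeros_like(vals)
    pos = vals > 0
    out[pos] = np.log(vals[pos]) / np.log(base)
    sub_one = pos & (vals < 1)
    if sub_one.any():
        warnings.warn(
            f"{int(sub_one.sum())} sub-1 raw intensities floored to 0 after log transform",
            stacklevel=2,
        )
        out[sub_one] = 0.0
    transformed = pd.DataFrame(out, index=table.intensities.index,
                               columns=table.intensities.columns)
    return FeatureTable(table.features.copy(), transformed.clip(lower=0.0))


def estimate_presence_cutoff(values: np.ndarray | pd.DataFrame, q: float = 0.05) -> float:
    """Lower q-tail of a normal fitted to the positive transformed intensities.

    cutoff = mean + z_q * sd, with the (n-1)-denominator sample sd and z_q the
    standard-normal q-quantile (z_0.05 ~ -1.6449).
    """
    if not 0 < q < 1:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    arr = np.asarray(values, dtype=float).ravel()
    pos = arr[arr > 0]
    if pos.size == 0:
        raise DegenerateDataError("all values are zero; no intensity distribution to fit")
    if pos.size < 2:
        raise DegenerateDataError("need at least 2 positive values to fit a cutoff")
    mu = float(pos.mean())
    sd = float(pos.std(ddof=1))
    if sd == 0.0:
        warnings.warn("degenerate intensity distribution (sd = 0); cutoff set to the mean",
                      stacklevel=2)
        return mu
    return mu + float(stats.norm.ppf(q)) * sd


def to_presence_matrix(table: FeatureTable, cutoff: float, q: float = 0.05) -> PresenceMatrix:
    """Threshold a transformed table: entry 1 iff intensity >= cutoff.

    The boundary is inclusive: an intensity exactly at the cutoff counts as
    present.
    """
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    binary = (table.intensities >= cutoff).astype(int)
    return PresenceMatrix(binary, cutoff=float(cutoff), q=q)


def combine_monoculture_pairs(
    table: FeatureTable,
    pheno: PhenoData,
    species: str,
    compartment: str,
    polarity: str,
    pairing: list[tuple[int, int]] | None = None,
) -> tuple[FeatureTable, PhenoData]:
    """Sum mono-culture replicate pairs into half as many pseudo-replicates.

    Replicates of the selected (species, compartment, polarity) mono-culture
    group are sorted by replicate index and paired (1,2), (3,4), ...; each
    pseudo-sample's intensity is the pair sum on the *untransformed* scale.
    Pseudo-sample ids are suffixed ``_comb{k}``.  An explicit ``pairing`` of
    replicate indices overrides the default ascending pairing.

    Returns the pseudo-sample feature table and matching phenodata rows.
    """
    sel = pheno.table[
        (pheno.table["species"] == species)
        & (pheno.table["compartment"] == compartment)
        & (pheno.table["polarity"] == polarity)
        & (pheno.table["culture"] == "mono")
    ]
    if sel.empty:
        raise ValidationError(
            f"no mono-culture samples for ({species}, {compartment}, {polarity})"
        )
    by_rep = sel.sort_values("replicate")
    reps = by_rep["replicate"].tolist()
    if pairing is None:
        if len(reps) % 2 != 0:
            raise ValidationError(
                f"odd mono-culture replicate count ({len(reps)}) cannot be paired"
            )
        pairing = [(reps[i], reps[i + 1]) for i in range(0, len(reps), 2)]
    rep_to_sample = dict(zip(by_rep["replicate"], by_rep.index))
    cols = {}
    rows = []
    for k, (r1, r2) in enumerate(pairing, start=1):
        for r in (r1, r2):
            if r not in rep_to_sample:
                raise ValidationError(f"replicate {r} absent from the mono-culture group")
        sid = f"{species}_{compartment}_{polarity}_mono_comb{k}"
        cols[sid] = (
            table.intensities[rep_to_sample[r1]] + table.intensities[rep_to_sample[r2]]
        )
        rows.append(
            {
                "sample_id": sid,
                "species": species,
                "compartment": compartment,
                "culture": "mono",
                "polarity": polarity,
                "replicate": k,
            }
        )
    pseudo = pd.DataFrame(cols, index=table.intensities.index)
    pseudo_pheno = PhenoData(pd.DataFrame(rows).set_index("sample_id"))
    return FeatureTable(table.features.copy(), pseudo), pseudo_pheno
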
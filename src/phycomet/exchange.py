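"""Metabolic-exchange classification of differential co-culture endometabolome features.

For each differentially produced feature of the focal species' co-culture
endometabolome, its presence/absence is looked up across the *partner*
species' conditions (exometabolome mono, endometabolome mono, endometabolome
co; the shared co-culture exometabolome is recorded but never enters the
rules, since it cannot be attributed to one species).  The occurrence pattern
is mapped to one of five categories:

EXCLUSIVE_CO
    absent from every queried partner condition — produced only by the focal
    species in co-culture;
PARTNER_RELEASED
    present only in the partner's mono-culture exometabolome — released by
    the partner and taken up by the focal species;
PARTNER_ENDOGENOUS
    present in both partner endometabolomes but not its released fraction;
SHARED_ALL
    present in all queried partner conditions;
MIXED
    any other pattern (reported with the raw flags so overlapping narrative
    counts remain derivable).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .preprocess import PresenceMatrix
from .tables_io import PhenoData

CATEGORIES = ("EXCLUSIVE_CO", "PARTNER_RELEASED", "PARTNER_ENDOGENOUS", "SHARED_ALL", "MIXED")
_PARTNER = {"SM": "PP", "PP": "SM"}


def condition_presence(
    presence: PresenceMatrix, pheno: PhenoData, min_fraction: float = 0.5
) -> pd.DataFrame:
    """Collapse replicate presence to condition presence by a fraction rule.

    A feature is present in a condition (species, compartment, culture) iff it
    is present in at least ``max(1, ceil(min_fraction * n_replicates))``
    replicates — an inclusive at-least-half rule at the default 0.5 (2 of 4
    replicates counts as present), and any single replicate at
    ``min_fraction = 0``.  The inclusive boundary keeps condition calls robust
    under replicate dropout: with 4-replicate co-cultures, requiring a strict
    majority (3 of 4) would lose ~18% of genuinely present calls at 20%
    dropout.  Columns are named ``{species}_{compartment}_{culture}``.
    """
    if not 0 <= min_fraction <= 1:
        raise ValidationError("min_fraction must lie in [0, 1]")
    cols = {}
    ph = pheno.table[pheno.table["species"] != "BLANK"]
    for (sp, comp, cult), sub in ph.groupby(["species", "compartment", "culture"], sort=True):
        samples = [s for s in sub.index if s in presence.matrix.columns]
        if not samples:
            raise ValidationError(f"condition ({sp}, {comp}, {cult}) has zero samples")
        needed = max(1, math.ceil(min_fraction * len(samples) - 1e-9))
        count = presence.matrix[samples].sum(axis=1)
        cols[f"{sp}_{comp}_{cult}"] = (count >= needed).astype(int)
    return pd.DataFrame(cols, index=presence.matrix.index)


@dataclass
class ExchangeResult:
    feature_id: str
    focal_species: str
    partner_exo_mono: int
    partner_endo_mono: int
    partner_endo_co: int
    partner_exo_co: int
    category: str


def classify_pattern(exo_mono: int, endo_mono: int, endo_co: int) -> str:
    """Category from the three queried partner flags; pure and deterministic.

    Precedence: exclusive -> shared-all -> released -> endogenous -> mixed.
    """
    if not (exo_mono or endo_mono or endo_co):
        return "EXCLUSIVE_CO"
    if exo_mono and endo_mono and endo_co:
        return "SHARED_ALL"
    if exo_mono and not endo_mono and not endo_co:
        return "PARTNER_RELEASED"
    if endo_mono and endo_co and not exo_mono:
        return "PARTNER_ENDOGENOUS"
    return "MIXED"


def classify_exchange(
    differential: list[str],
    presence: pd.DataFrame,
    focal: str,
) -> list[ExchangeResult]:
    """Classify each differential feature of the focal co-culture endometabolome.

    ``presence`` is the condition-presence table from
    :func:`condition_presence`; ``focal`` is 'SM' or 'PP' (the partner is the
    other species).
    """
    if focal not in _PARTNER:
        raise ValidationError(f"unknown focal species {focal!r}; expected SM or PP")
    partner = _PARTNER[focal]
    needed = [f"{partner}_exo_mono", f"{partner}_endo_mono",
              f"{partner}_endo_co", f"{partner}_exo_co"]
    missing_cols = [c for c in needed if c not in presence.columns]
    if missing_cols:
        raise ValidationError(f"presence table missing condition column(s): {missing_cols}")
    missing_feats = [f for f in differential if f not in presence.index]
    if missing_feats:
        raise ValidationError(f"differential feature(s) absent from presence table: "
                              f"{missing_feats[:5]}")
    out = []
    for fid in differential:
        row = presence.loc[fid, needed]
        exo_mono, endo_mono, endo_co, exo_co = (int(v) for v in row)
        out.append(
            ExchangeResult(
                feature_id=fid,
                focal_species=focal,
                partner_exo_mono=exo_mono,
                partner_endo_mono=endo_mono,
                partner_endo_co=endo_co,
                partner_exo_co=exo_co,
                category=classify_pattern(exo_mono, endo_mono, endo_co),
            )
        )
    return out


def summarize_exchange(results: list[ExchangeResult]) -> pd.DataFrame:
    """Category counts (all categories present, zero-filled) with a partition check."""
    counts = Counter(r.category for r in results)
    unknown = set(counts) - set(CATEGORIES)
    assert not unknown, f"unknown categories {unknown}"
    out = pd.DataFrame(
        {"count": [counts.get(c, 0) for c in CATEGORIES]},
        index=pd.Index(CATEGORIES, name="category"),
    )
    assert int(out["count"].sum()) == len(results), "categories must partition the input"
    return out


def exchange_frame(results: list[ExchangeResult]) -> pd.DataFrame:
    """Flat table: feature_id, focal species, the 4 pattern flags, category."""
    return pd.DataFrame(
        [{
            "feature_id": r.feature_id,
            "focal_species": r.focal_species,
            "partner_exo_mono": r.partner_exo_mono,
            "partner_endo_mono": r.partner_endo_mono,
            "partner_endo_co": r.partner_endo_co,
            "partner_exo_co": r.partner_exo_co,
            "category": r.category,
        } for r in results]
    )
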
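"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the non-contact co-culture design: 2 species (SM, a
diatom; PP, a haptophyte) x {endo, exo} compartments x {mono: 8 replicates,
co: 4 replicates}, one ionisation polarity per dataset.  Feature intensities
are log-normal with zero inflation; differential features carry a controlled
log2 shift in the co-culture condition; exchange features realise chosen
occurrence patterns across the partner species' conditions; inclusion lists
jitter precursor m/z within the feature envelopes; growth curves are logistic
with a multiplicative co-culture suppression factor.

Two seeds decouple *what is planted* (``design_seed``: memberships,
categories) from *how noise realises* (``noise_seed``), so power curves can
vary noise while holding the truth fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .tables_io import FeatureTable, GrowthSeries, PhenoData, SuspectEntry
from .annotation_linking import AnnotationRecord, InclusionEntry

SPECIES = ("SM", "PP")
COMPARTMENTS = ("endo", "exo")

# emulated occurrence partitions of the differential co-culture endometabolome
# features: 30 for the haptophyte focal direction, 15 for the diatom direction
DEFAULT_EXCHANGE_DESIGN = {
    "PP": {"EXCLUSIVE_CO": 7, "PARTNER_RELEASED": 10,
           "PARTNER_ENDOGENOUS": 6, "SHARED_ALL": 7},
    "SM": {"EXCLUSIVE_CO": 7, "PARTNER_RELEASED": 5, "SHARED_ALL": 3},
}

# small pool of microalgal metabolites used to label synthetic annotations
# and suspect entries (name, SMILES, source species)
_COMPOUND_POOL = [
    ("fucoxanthin", "CC1(C)CC(O)CC(C)(C)C1=C=CC(C)=CC=CC(C)=CC=CC=C(C)C=CC=C(C)C(=O)CC2(O)CC(O)CC2(C)C", "BOTH"),
    ("monomyristin", "CCCCCCCCCCCCCC(=O)OCC(O)CO", "BOTH"),
    ("monopalmitin", "CCCCCCCCCCCCCCCC(=O)OCC(O)CO", "BOTH"),
    ("toluene", "Cc1ccccc1", "SM"),
    ("octatrienal", "CC=CC=CC=CC=O", "SM"),
    ("7-mercaptoheptanoic acid", "OC(=O)CCCCCCS", "SM"),
    ("hexadeca-6,9,12-trienoic acid", "CCCC=CCC=CCC=CCCCCC(O)=O", "SM"),
    ("viburnitol", "OC1CC(O)C(O)C(O)C1O", "PP"),
    ("cytosine", "Nc1cc[nH]c(=O)n1", "PP"),
    ("monolaurin", "CCCCCCCCCCCC(=O)OCC(O)CO", "PP"),
]


@dataclass
class GeneratorConfig:
    """Stated world of the synthetic co-culture LC-MS experiment.

    Defaults mirror the emulated design (8 mono / 4 co replicates, RT range
    inside 0-700 s) and, where the emulated study states no value, a choice
    documented in the methods note: baseline log2 intensity ~ N(20, 2),
    replicate noise sd 1 (log2), 10% zero inflation, planted log2 effect 2
    (= 2 x noise sd), 20 differential features per contrast out of 500.
    """

    n_features: int = 500
    mono_replicates: int = 8
    co_replicates: int = 4
    polarity: str = "pos"
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    noise_sd: float = 1.0
    zero_inflation: float = 0.1
    effect_size: float = 2.0
    n_differential: int = 20
    exchange_design: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EXCHANGE_DESIGN.items()}
    )
    mz_range: tuple[float, float] = (100.0, 1200.0)
    rt_range: tuple[float, float] = (20.0, 680.0)
    design_seed: int = 0
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.zero_inflation <= 1:
            raise ValidationError("zero_inflation must lie in [0, 1]")
        if self.mono_replicates < 2 or self.co_replicates < 2:
            raise ValidationError("replicate counts must be >= 2")
        if not (0 <= self.rt_range[0] < self.rt_range[1] <= 700):
            raise ValidationError("rt_range must lie within [0, 700] seconds")
        n_exchange = sum(sum(d.values()) for d in self.exchange_design.values())
        n_planted = n_exchange + self.n_differential * len(SPECIES) * len(COMPARTMENTS)
        if n_planted > self.n_features:
            raise ValidationError(
                f"{n_planted} planted features exceed n_features={self.n_features}"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    differential: dict[tuple[str, str], dict[str, float]]  # (species, compartment) -> id -> log2 effect
    exchange_categories: dict[str, dict[str, str]]         # focal species -> id -> category
    fragmented_features: list[str] = field(default_factory=list)
    annotation_features: list[str] = field(default_factory=list)  # parallel to annotation list
    growth_effect: dict[str, float] = field(default_factory=dict)
    design_seed: int = 0
    noise_seed: int = 0


def _design_samples(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for sp in SPECIES:
        for comp in COMPARTMENTS:
            for cult, n_rep in (("mono", config.mono_replicates), ("co", config.co_replicates)):
                for rep in range(1, n_rep + 1):
                    sid = f"{sp}_{comp}_{cult}_{config.polarity}_{rep}"
                    rows.append({"sample_id": sid, "species": sp, "compartment": comp,
                                 "culture": cult, "polarity": config.polarity,
                                 "replicate": rep})
    return pd.DataFrame(rows).set_index("sample_id")


# occurrence flags per exchange category, keyed by partner condition
# (exo_mono, endo_mono, endo_co, exo_co)
_CATEGORY_FLAGS = {
    "EXCLUSIVE_CO": (0, 0, 0, 0),
    "PARTNER_RELEASED": (1, 0, 0, 1),
    "PARTNER_ENDOGENOUS": (0, 1, 1, 0),
    "SHARED_ALL": (1, 1, 1, 1),
}


def generate_feature_dataset(
    config: GeneratorConfig,
) -> tuple[FeatureTable, PhenoData, SyntheticTruth]:
    """Generate a feature table + phenodata with planted differential and
    exchange structure; bitwise reproducible given the config seeds.

    Differential features receive a ``effect_size`` log2 shift in the
    co-culture samples of their (species, compartment) contrast.  Exchange
    features are additional co-enriched differential features of the focal
    species' endometabolome whose presence across the partner's conditions is
    constructed to match the planted category.  Planted features draw their
    baseline from the upper part of the intensity distribution (truncated at
    mean - 1 sd), emulating that differential/fragmented features are
    reliably detected peaks.
    """
    rng_design = np.random.default_rng(config.design_seed)
    rng_noise = np.random.default_rng(config.noise_seed)
    pheno_df = _design_samples(config)
    samples = pheno_df.index
    n, m = config.n_features, len(samples)
    feature_ids = [f"FT{i + 1:05d}" for i in range(n)]

    # -- planted memberships (design seed) ---------------------------------
    n_exchange = {sp: sum(d.values()) for sp, d in config.exchange_design.items()}
    n_planted = sum(n_exchange.values()) + config.n_differential * len(SPECIES) * len(COMPARTMENTS)
    planted_pool = rng_design.choice(n, size=n_planted, replace=False)
    cursor = 0
    differential: dict[tuple[str, str], dict[str, float]] = {}
    exchange_categories: dict[str, dict[str, str]] = {}
    exchange_ids: dict[str, list[tuple[str, str]]] = {}
    for sp in SPECIES:
        for comp in COMPARTMENTS:
            idx = planted_pool[cursor:cursor + config.n_differential]
            cursor += config.n_differential
            differential[(sp, comp)] = {feature_ids[i]: config.effect_size for i in idx}
    for sp, design in config.exchange_design.items():
        cats: dict[str, str] = {}
        pairs: list[tuple[str, str]] = []
        for cat, count in design.items():
            if cat not in _CATEGORY_FLAGS:
                raise ValidationError(f"unknown exchange category {cat!r}")
            idx = planted_pool[cursor:cursor + count]
            cursor += count
            for i in idx:
                cats[feature_ids[i]] = cat
                pairs.append((feature_ids[i], cat))
        exchange_categories[sp] = cats
        exchange_ids[sp] = pairs
        differential[(sp, "endo")].update({fid: config.effect_size for fid in cats})

    planted_set = {feature_ids[i] for i in planted_pool}

    # -- envelopes (design seed) -------------------------------------------
    mz_med = rng_design.uniform(*config.mz_range, size=n)
    rt_med = rng_design.uniform(*config.rt_range, size=n)
    features = pd.DataFrame(
        {
            "mz_min": mz_med * (1 - 10e-6),
            "mz_med": mz_med,
            "mz_max": mz_med * (1 + 10e-6),
            "rt_min": np.clip(rt_med - 15, 0, None),
            "rt_med": rt_med,
            "rt_max": np.clip(rt_med + 15, None, 700.0),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )

    # -- baselines ----------------------------------------------------------
    baseline = rng_design.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    planted_idx = np.array(sorted(planted_pool))
    if planted_idx.size and config.baseline_log2_sd > 0:
        baseline[planted_idx] = stats.truncnorm.rvs(
            a=-1.0, b=np.inf,
            loc=config.baseline_log2_mean, scale=config.baseline_log2_sd,
            size=planted_idx.size, random_state=rng_design,
        )

    # -- intensities (noise seed) -------------------------------------------
    log2 = baseline[:, None] + rng_noise.normal(0.0, config.noise_sd, size=(n, m))
    id_to_row = {fid: i for i, fid in enumerate(feature_ids)}
    col_groups: dict[tuple[str, str, str], np.ndarray] = {}
    for key, sub in pheno_df.groupby(["species", "compartment", "culture"], sort=False):
        col_groups[key] = np.array([samples.get_loc(s) for s in sub.index])
    for (sp, comp), effects in differential.items():
        cols = col_groups[(sp, comp, "co")]
        for fid, eff in effects.items():
            log2[id_to_row[fid]][cols] += eff

    present = np.ones((n, m), dtype=bool)
    for sp, pairs in exchange_ids.items():
        partner = "PP" if sp == "SM" else "SM"
        for fid, cat in pairs:
            row = id_to_row[fid]
            exo_mono, endo_mono, endo_co, exo_co = _CATEGORY_FLAGS[cat]
            flags = {
                (partner, "exo", "mono"): exo_mono,
                (partner, "endo", "mono"): endo_mono,
                (partner, "endo", "co"): endo_co,
                (partner, "exo", "co"): exo_co,
                (sp, "endo", "mono"): 0,     # differential: only abundant in co-culture
                (sp, "endo", "co"): 1,
                (sp, "exo", "mono"): 0,
                (sp, "exo", "co"): exo_co,   # shared medium: both sides agree
            }
            for key, flag in flags.items():
                if not flag:
                    present[row, col_groups[key]] = False

    if config.zero_inflation > 0:
        present &= rng_noise.random((n, m)) >= config.zero_inflation
    raw = np.where(present, np.exp2(log2), 0.0)

    intensities = pd.DataFrame(raw, index=features.index, columns=samples)
    table = FeatureTable(features, intensities)
    pheno = PhenoData(pheno_df)
    truth = SyntheticTruth(
        differential=differential,
        exchange_categories=exchange_categories,
        design_seed=config.design_seed,
        noise_seed=config.noise_seed,
    )
    return table, pheno, truth


def generate_inclusion_and_annotations(
    table: FeatureTable,
    truth: SyntheticTruth,
    fraction: float = 0.3,
    seed: int = 0,
    ppm_jitter: float = 3.0,
    rt_halfwidth: float = 30.0,
    annotated_fraction: float = 0.8,
    polarity: str = "pos",
) -> tuple[list[InclusionEntry], list[AnnotationRecord]]:
    """Inclusion entries (jittered precursor + RT window) for a random subset
    of features, and annotation records for a subset of those entries.

    The precursor m/z is the feature's median m/z jittered by at most
    ``ppm_jitter`` ppm (inside the +/-10 ppm envelope); the RT window is
    rt_med +/- ``rt_halfwidth`` s.  MSI levels are sampled over {2, 3, 4, 5}
    with spectral-match (2) rare and compound-database candidates (3)
    dominant.  ``truth`` records which features were fragmented and which
    feature each annotation belongs to.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    ids = list(table.feature_ids)
    # planted differential features are the high-intensity peaks an
    # inclusion list targets; always fragment them, fill up at random
    planted = sorted({fid for d in truth.differential.values() for fid in d})
    n_total = max(len(planted), int(round(fraction * len(ids))))
    others = [f for f in ids if f not in set(planted)]
    extra = list(rng.choice(others, size=min(len(others), n_total - len(planted)),
                            replace=False)) if n_total > len(planted) else []
    chosen = sorted(set(planted) | set(extra), key=ids.index) if fraction < 1 else ids

    inclusion: list[InclusionEntry] = []
    for fid in chosen:
        row = table.features.loc[fid]
        prec = row["mz_med"] * (1 + rng.uniform(-ppm_jitter, ppm_jitter) * 1e-6)
        inclusion.append(
            InclusionEntry(
                precursor_mz=float(prec),
                rt_min=float(max(0.0, row["rt_med"] - rt_halfwidth)),
                rt_max=float(min(700.0, row["rt_med"] + rt_halfwidth)),
                polarity=polarity,
            )
        )
    truth.fragmented_features = list(chosen)

    msi_levels = np.array([2, 3, 4, 5])
    msi_probs = np.array([0.08, 0.6, 0.17, 0.15])
    n_ann = int(round(annotated_fraction * len(chosen)))
    ann_pick = sorted(rng.choice(len(chosen), size=n_ann, replace=False))
    annotations: list[AnnotationRecord] = []
    ann_features: list[str] = []
    endo_cols = [s for s in table.sample_ids if "_endo_" in s]
    exo_cols = [s for s in table.sample_ids if "_exo_" in s]
    for k, j in enumerate(ann_pick):
        fid, entry = chosen[j], inclusion[j]
        level = int(rng.choice(msi_levels, p=msi_probs))
        name, smiles, _src = _COMPOUND_POOL[k % len(_COMPOUND_POOL)]
        endo_mean = float(table.intensities.loc[fid, endo_cols].mean()) if endo_cols else 0.0
        exo_mean = float(table.intensities.loc[fid, exo_cols].mean()) if exo_cols else 0.0
        comp = "endo" if endo_mean >= exo_mean else "exo"
        annotations.append(
            AnnotationRecord(
                precursor_mz=float(entry.precursor_mz * (1 + rng.uniform(-1, 1) * 1e-6)),
                rt=float(np.clip(
                    table.features.loc[fid, "rt_med"] + rng.uniform(-10, 10),
                    entry.rt_min, entry.rt_max,
                )),
                name=name if level <= 3 else "",
                smiles=smiles if level <= 3 else "",
                chemont_class="synthetic class",
                msi_level=level,
                source={2: "spectral_db", 3: "compound_db"}.get(level, "none"),
                condition=("", comp, polarity),
            )
        )
        ann_features.append(fid)
    truth.annotation_features = ann_features
    return inclusion, annotations


def synthetic_suspect_list(n: int = 222, seed: int = 0) -> list[SuspectEntry]:
    """A synthetic suspect list: the small named pool plus generated filler
    entries (simple alkane/alcohol SMILES), emulating a curated per-organism
    catalogue of a few hundred metabolites."""
    rng = np.random.default_rng(seed)
    entries: list[SuspectEntry] = []
    for name, smiles, src in _COMPOUND_POOL[:n]:
        entries.append(SuspectEntry(name=name, smiles=smiles, source_species=src))
    for i in range(len(entries), n):
        length = int(rng.integers(5, 25))
        smiles = "C" * length if i % 2 == 0 else "OC" + "C" * length
        entries.append(
            SuspectEntry(
                name=f"synthetic metabolite {i + 1:03d}",
                smiles=smiles,
                monoisotopic_mass=float(14.0157 * length + 2.016),
                source_species=("SM", "PP", "BOTH")[i % 3],
            )
        )
    return entries


def logistic_rfu(day: float, K: float, r: float, t0: float) -> float:
    return K / (1.0 + np.exp(-r * (day - t0)))


def generate_growth_curves(
    K: float = 3000.0,
    r: float = 0.9,
    t0: float = 4.0,
    suppression: float = 1.0,
    noise_sd: float = 100.0,
    replicates: tuple[int, int] = (8, 4),
    seed: int = 0,
    species: str = "SM",
    late_factor: float = 1.0,
    late_from_day: int | None = None,
    days: tuple[int, ...] = (0, 2, 4, 6, 8),
) -> list[GrowthSeries]:
    """Logistic growth curves with a multiplicative co-culture suppression.

    RFU(day) = K / (1 + exp(-r (day - t0))), times ``suppression`` for
    co-culture replicates, plus Gaussian noise truncated at 0.  The optional
    ``late_factor`` applies to co-culture from ``late_from_day`` onward,
    emulating a response confined to the end of the experiment.
    ``replicates`` is (mono, co).
    """
    if K <= 0:
        raise ValidationError("carrying capacity K must be > 0")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if not 0 < suppression <= 1:
        raise ValidationError("suppression factor must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out: list[GrowthSeries] = []
    for culture, n_rep in (("mono", replicates[0]), ("co", replicates[1])):
        for rep in range(1, n_rep + 1):
            obs = {}
            for day in days:
                mean = logistic_rfu(day, K, r, t0)
                if culture == "co":
                    mean *= suppression
                    if late_from_day is not None and day >= late_from_day:
                        mean *= late_factor
                val = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                obs[day] = max(0.0, float(val))
            out.append(GrowthSeries(species=species, culture=culture,
                                    replicate=rep, observations=obs))
    return out


# deterministic unit-sd, zero-mean replicate deviation patterns
_P4 = np.array([-3.0, -1.0, 1.0, 3.0]) / np.sqrt(20.0 / 3.0)
_P8 = np.concatenate([_P4, _P4[::-1]])  # replicates 1-4 reproduce _P4 exactly


def s1_style_growth_table(
    cv: float = 0.05,
    sm_K: float = 3500.0,
    pp_K: float = 3000.0,
    r: float = 0.9,
    t0: float = 4.0,
    sm_suppression: float = 0.7,
    pp_day8_shift: float = 290.0,
) -> list[GrowthSeries]:
    """Synthetic, deterministic stand-in for the supplementary fluorescence table.

    Constructs 8 mono + 4 co replicates per species on days 0-8 with planted
    per-day means (logistic curves) and exact per-day dispersions
    (sd = cv x mean, realised by fixed zero-mean unit-sd deviation patterns).
    Planted narrative: the diatom's co-culture is suppressed across all days
    (factor ``sm_suppression``); the haptophyte is unaffected except for a
    day-8 RFU increase of ``pp_day8_shift``.  Being constructed rather than
    simulated, the resulting ANOVA/Welch statistics are deterministic.
    """
    out: list[GrowthSeries] = []
    for sp, K in (("SM", sm_K), ("PP", pp_K)):
        for culture, n_rep, pattern in (("mono", 8, _P8), ("co", 4, _P4)):
            for i in range(n_rep):
                obs = {}
                for day in (0, 2, 4, 6, 8):
                    mean = logistic_rfu(day, K, r, t0)
                    if culture == "co":
                        if sp == "SM":
                            mean *= sm_suppression
                        elif day == 8:
                            mean += pp_day8_shift
                    sd = cv * mean
                    obs[day] = float(mean + sd * pattern[i])
                out.append(GrowthSeries(species=sp, culture=culture,
                                        replicate=i + 1, observations=obs))
    return out
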
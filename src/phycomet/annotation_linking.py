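"""Resolve MS2 annotations to MS1 feature IDs through DDA inclusion lists.

An inclusion list carries the precursor m/z values (with retention-time
windows) that triggered MS2 fragmentation.  Linking is two interval checks:
a precursor matches a feature when the precursor m/z lies inside the feature's
m/z envelope (``mz_min <= precursor <= mz_max``), and the match is *full* when
the feature's median retention time additionally lies inside the inclusion
window; otherwise the feature id is still assigned with status ``mz_only`` and
a machine-readable comment recording the RT mismatch.  Structure annotations
(precursor m/z + RT + SMILES/name/class + MSI confidence level) inherit the
feature id of the inclusion precursor they match within a ppm tolerance.

Downstream helpers tally annotations per MSI confidence level (level 2 =
spectral-library match, 3 = compound-database candidate, 4/5 = class/formula/
unknown, pooled) and screen annotations against per-organism suspect lists by
structure key (InChIKey connectivity block) first, compound name second.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DegenerateDataError, ValidationError
from .pls_select import SelectionResult
from .tables_io import FeatureTable, SuspectEntry


@dataclass(frozen=True)
class InclusionEntry:
    precursor_mz: float
    rt_min: float
    rt_max: float
    polarity: str = "pos"

    def __post_init__(self) -> None:
        if not self.precursor_mz > 0:
            raise ValidationError(f"precursor m/z must be > 0, got {self.precursor_mz}")
        if self.rt_min > self.rt_max:
            raise ValidationError("inclusion RT window has rt_min > rt_max")


@dataclass
class AnnotationRecord:
    precursor_mz: float
    rt: float
    name: str = ""
    smiles: str = ""
    formula: str = ""
    chemont_class: str = ""
    msi_level: int = 5
    source: str = "none"  # spectral_db | compound_db | none
    condition: tuple[str, str, str] = ("", "", "")  # (species attribution, compartment, polarity)

    def __post_init__(self) -> None:
        if self.msi_level not in (2, 3, 4, 5):
            raise ValidationError(f"MSI level must be 2-5, got {self.msi_level}")
        if self.msi_level == 2 and self.source != "spectral_db":
            raise ValidationError("MSI level 2 requires source=spectral_db")
        if self.msi_level == 3 and self.source != "compound_db":
            raise ValidationError("MSI level 3 requires source=compound_db")


@dataclass
class LinkResult:
    entry: InclusionEntry
    feature_id: str | None
    match_status: str  # full | mz_only | unlinked
    comment: str = ""


@dataclass
class LinkedAnnotation:
    record: AnnotationRecord
    feature_id: str | None = None
    match_status: str = "unlinked"
    comment: str = ""


def link_inclusion_to_features(
    inclusion: list[InclusionEntry], features: FeatureTable
) -> list[LinkResult]:
    """Assign a feature id to every inclusion precursor by interval containment.

    Candidates are features whose m/z envelope encloses the precursor; among
    them, features whose median RT falls inside the inclusion window give a
    ``full`` match.  Ties (several enclosing features) are broken by minimal
    |mz_med - precursor|, then minimal |rt_med - window midpoint|; losing
    candidates are listed in the comment.  Precursors with no enclosing
    envelope are ``unlinked``.  Deterministic and order-independent.
    """
    if len(features.feature_ids) == 0:
        raise DegenerateDataError("empty feature table")
    f = features.features
    results: list[LinkResult] = []
    for entry in inclusion:
        cand = f[(f["mz_min"] <= entry.precursor_mz) & (entry.precursor_mz <= f["mz_max"])]
        if cand.empty:
            results.append(LinkResult(entry, None, "unlinked",
                                      "no feature m/z envelope encloses the precursor"))
            continue
        in_rt = cand[(entry.rt_min <= cand["rt_med"]) & (cand["rt_med"] <= entry.rt_max)]
        pool = in_rt if not in_rt.empty else cand
        mid = 0.5 * (entry.rt_min + entry.rt_max)
        order = pool.assign(
            _dmz=(pool["mz_med"] - entry.precursor_mz).abs(),
            _drt=(pool["rt_med"] - mid).abs(),
        ).sort_values(["_dmz", "_drt"], kind="mergesort")  # stable: row order breaks exact ties
        winner = order.index[0]
        losers = [str(i) for i in order.index[1:]]
        parts = []
        if in_rt.empty:
            status = "mz_only"
            parts.append(
                f"rt_med {f.loc[winner, 'rt_med']:g}s outside inclusion window "
                f"[{entry.rt_min:g}, {entry.rt_max:g}]s"
            )
        else:
            status = "full"
        if losers:
            parts.append("other m/z-enclosing candidates: " + ", ".join(losers))
        results.append(LinkResult(entry, str(winner), status, "; ".join(parts)))
    return results


def link_annotations_to_features(
    annotations: list[AnnotationRecord],
    link_map: list[LinkResult],
    ppm_tolerance: float = 5.0,
) -> list[LinkedAnnotation]:
    """Match annotation precursors to inclusion precursors and inherit feature ids.

    An annotation matches an inclusion entry when its precursor m/z is within
    ``ppm_tolerance`` of the entry's precursor and its RT lies inside the
    entry's window; the closest precursor (in ppm) wins.  Unmatched
    annotations are kept with status ``unlinked`` — no annotation is lost.
    """
    out: list[LinkedAnnotation] = []
    for rec in annotations:
        best: LinkResult | None = None
        best_ppm = float("inf")
        for link in link_map:
            ppm = abs(rec.precursor_mz - link.entry.precursor_mz) / link.entry.precursor_mz * 1e6
            if ppm <= ppm_tolerance and link.entry.rt_min <= rec.rt <= link.entry.rt_max:
                if ppm < best_ppm:
                    best, best_ppm = link, ppm
        if best is None or best.feature_id is None:
            out.append(LinkedAnnotation(rec, None, "unlinked",
                                        "no inclusion precursor within tolerance"))
        else:
            out.append(LinkedAnnotation(rec, best.feature_id, best.match_status, best.comment))
    return out


def tally_msi_levels(
    linked: list[LinkedAnnotation],
    selections: dict[str, "SelectionResult | set[str]"] | None = None,
) -> pd.DataFrame:
    """Per-condition counts of annotations by MSI confidence level.

    Columns: total, msi2, msi3, msi45 (levels 4 and 5 pooled), and — when a
    per-species ``selections`` mapping ({'SM': ..., 'PP': ...}, each a
    SelectionResult or a plain feature-id set) is given — counts of linked
    annotations whose feature id was differentially selected for each species.
    """
    rows: dict[tuple, dict] = {}
    diff_sets = {
        sp: set(sel.selected) if isinstance(sel, SelectionResult) else set(sel)
        for sp, sel in (selections or {}).items()
    }
    for la in linked:
        key = la.record.condition[1:]  # (compartment, polarity)
        row = rows.setdefault(
            key,
            {"total": 0, "msi2": 0, "msi3": 0, "msi45": 0,
             **{f"n_differential_{sp}": 0 for sp in diff_sets}},
        )
        row["total"] += 1
        lvl = la.record.msi_level
        row["msi2" if lvl == 2 else "msi3" if lvl == 3 else "msi45"] += 1
        for sp, ids in diff_sets.items():
            if la.feature_id is not None and la.feature_id in ids:
                row[f"n_differential_{sp}"] += 1
    if not rows:
        cols = ["total", "msi2", "msi3", "msi45"]
        return pd.DataFrame(columns=cols, dtype=int)
    out = pd.DataFrame(rows).T.sort_index()
    out.index = ["_".join(k) for k in out.index]
    out.index.name = "condition"
    return out.astype(int)


# ---------------------------------------------------------------------------
# suspect screening
# ---------------------------------------------------------------------------

def _inchikey_block(smiles: str = "", inchi: str = "") -> str | None:
    """First (connectivity) block of the InChIKey, or None if unavailable."""
    try:
        from rdkit import Chem
        from rdkit.rdBase import BlockLogs
    except ImportError:  # pragma: no cover - rdkit is an optional extra
        return None
    with_logs_off = BlockLogs()
    mol = None
    if smiles:
        mol = Chem.MolFromSmiles(smiles)
    if mol is None and inchi:
        mol = Chem.MolFromInchi(inchi)
    del with_logs_off
    if mol is None:
        return None
    key = Chem.MolToInchiKey(mol)
    return key.split("-")[0] if key else None


@dataclass
class SuspectMatch:
    annotation: LinkedAnnotation
    suspect: SuspectEntry
    level: str  # 'structure' | 'name'
    source_species: str


def screen_suspects(
    linked: list[LinkedAnnotation], suspects: list[SuspectEntry]
) -> list[SuspectMatch]:
    """Screen linked annotations against suspect lists.

    Match levels, strongest first: equality of the InChIKey connectivity
    block computed from the structure identifiers, then case-insensitive name
    equality (reported at ``name`` level, never merged with structure
    matches).  Each match carries the suspect's source species.
    """
    sus_keys: list[str | None] = [
        _inchikey_block(s.smiles, s.inchi) if (s.smiles or s.inchi) else None
        for s in suspects
    ]
    matches: list[SuspectMatch] = []
    for la in linked:
        ann_key = _inchikey_block(la.record.smiles) if la.record.smiles else None
        hit_structure = False
        for s, key in zip(suspects, sus_keys):
            if ann_key is not None and key is not None and ann_key == key:
                matches.append(SuspectMatch(la, s, "structure", s.source_species))
                hit_structure = True
        if hit_structure:
            continue
        name = la.record.name.strip().casefold()
        if not name:
            continue
        for s in suspects:
            if s.name.strip().casefold() == name:
                matches.append(SuspectMatch(la, s, "name", s.source_species))
    return matches
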
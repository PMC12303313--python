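import numpy as np
import pytest

import phycomet as pm
from phycomet.annotation_linking import LinkResult
from phycomet.errors import DegenerateDataError, ValidationError

from conftest import make_feature_table


def entry(mz, rt_lo, rt_hi):
    return pm.InclusionEntry(precursor_mz=mz, rt_min=rt_lo, rt_max=rt_hi)


class TestInclusionLinking:
    def test_full_match_inside_both_windows(self):
        # styled on a real positive-mode precursor: 340.2467 m/z at 289 s
        table = make_feature_table([340.24675], [289.0], {"s1": [10.0]})
        table.features.loc["F1", ["mz_min", "mz_max"]] = [340.2460, 340.2475]
        [res] = pm.link_inclusion_to_features([entry(340.2467, 280, 300)], table)
        assert (res.feature_id, res.match_status) == ("F1", "full")

    def test_rt_mismatch_downgrades_with_comment(self):
        table = make_feature_table([340.24675], [350.0], {"s1": [10.0]})
        table.features.loc["F1", ["mz_min", "mz_max"]] = [340.2460, 340.2475]
        [res] = pm.link_inclusion_to_features([entry(340.2467, 280, 300)], table)
        assert (res.feature_id, res.match_status) == ("F1", "mz_only")
        assert "350" in res.comment and "300" in res.comment

    def test_no_envelope_is_unlinked(self):
        table = make_feature_table([340.24675], [289.0], {"s1": [10.0]})
        [res] = pm.link_inclusion_to_features([entry(999.9, 280, 300)], table)
        assert res.feature_id is None
        assert res.match_status == "unlinked"

    def test_empty_feature_table_errors(self):
        import pandas as pd
        table = make_feature_table([100.0], [50.0], {"s1": [1.0]})
        empty = pm.FeatureTable(table.features.iloc[:0], table.intensities.iloc[:0])
        with pytest.raises(DegenerateDataError):
            pm.link_inclusion_to_features([entry(100.0, 0, 100)], empty)

    def test_tie_break_prefers_closest_mz_and_lists_losers(self):
        table = make_feature_table([200.0, 200.001], [50.0, 52.0],
                                   {"s1": [1.0, 1.0]}, mz_halfwidth_ppm=20)
        [res] = pm.link_inclusion_to_features([entry(200.0008, 40, 60)], table)
        assert res.feature_id == "F2"  # mz_med 200.001 is closer to 200.0008
        assert "F1" in res.comment

    def test_order_independence(self):
        rng = np.random.default_rng(0)
        mz = rng.uniform(100, 1000, size=30)
        rt = rng.uniform(0, 700, size=30)
        table = make_feature_table(mz, rt, {"s1": np.ones(30)})
        entries = [entry(float(m * (1 + 2e-6)), float(r - 20), float(r + 20))
                   for m, r in zip(mz[:15], rt[:15])]
        fwd = pm.link_inclusion_to_features(entries, table)
        shuffled_table = pm.FeatureTable(
            table.features.sample(frac=1, random_state=1),
            table.intensities.sample(frac=1, random_state=1),
        )
        rev = pm.link_inclusion_to_features(entries[::-1], shuffled_table)[::-1]
        assert [(r.feature_id, r.match_status) for r in fwd] == [
            (r.feature_id, r.match_status) for r in rev
        ]


def brute_force_link(entries, table):
    """Independent all-pairs interval-containment oracle (plain loops)."""
    out = []
    feats = table.features
    for e in entries:
        enclosing = []
        for fid in feats.index:
            row = feats.loc[fid]
            if row["mz_min"] <= e.precursor_mz <= row["mz_max"]:
                enclosing.append(fid)
        if not enclosing:
            out.append((None, "unlinked"))
            continue
        in_rt = [fid for fid in enclosing
                 if e.rt_min <= feats.loc[fid, "rt_med"] <= e.rt_max]
        pool = in_rt if in_rt else enclosing
        mid = (e.rt_min + e.rt_max) / 2.0
        winner = sorted(
            pool,
            key=lambda fid: (abs(feats.loc[fid, "mz_med"] - e.precursor_mz),
                             abs(feats.loc[fid, "rt_med"] - mid),
                             list(feats.index).index(fid)),
        )[0]
        out.append((winner, "full" if in_rt else "mz_only"))
    return out


class TestLinkingOracle:
    def test_random_instances_match_brute_force(self):
        """Implementation output is identical to the all-pairs oracle."""
        rng = np.random.default_rng(99)
        n_instances = 200
        for _ in range(n_instances):
            n_feat = int(rng.integers(1, 12))
            mz = rng.uniform(100, 110, size=n_feat)  # narrow range to force overlaps
            rt = rng.uniform(0, 200, size=n_feat)
            table = make_feature_table(mz, rt, {"s1": np.ones(n_feat)},
                                       mz_halfwidth_ppm=rng.uniform(1, 200))
            entries = []
            for _ in range(int(rng.integers(1, 6))):
                m = rng.uniform(100, 110)
                lo = rng.uniform(0, 200)
                entries.append(entry(m, lo, lo + rng.uniform(0, 80)))
            got = [(r.feature_id, r.match_status)
                   for r in pm.link_inclusion_to_features(entries, table)]
            assert got == brute_force_link(entries, table)

    def test_full_status_sound_on_recheck(self):
        rng = np.random.default_rng(5)
        mz = rng.uniform(100, 105, size=40)
        rt = rng.uniform(0, 300, size=40)
        table = make_feature_table(mz, rt, {"s1": np.ones(40)}, mz_halfwidth_ppm=50)
        entries = [entry(float(m), float(r - 25), float(r + 25))
                   for m, r in zip(rng.uniform(100, 105, 30), rng.uniform(0, 300, 30))]
        for res in pm.link_inclusion_to_features(entries, table):
            if res.match_status == "full":
                row = table.features.loc[res.feature_id]
                assert row["mz_min"] <= res.entry.precursor_mz <= row["mz_max"]
                assert res.entry.rt_min <= row["rt_med"] <= res.entry.rt_max


class TestAnnotationLinking:
    def _setup(self):
        table = make_feature_table([340.24675], [289.0], {"s1": [10.0]})
        table.features.loc["F1", ["mz_min", "mz_max"]] = [340.2460, 340.2475]
        link_map = pm.link_inclusion_to_features([entry(340.2467, 280, 300)], table)
        return link_map

    def test_annotation_inherits_feature_id(self):
        ann = pm.AnnotationRecord(precursor_mz=340.2467, rt=289.0, name="tumonoic acid A",
                                  msi_level=3, source="compound_db")
        [la] = pm.link_annotations_to_features([ann], self._setup())
        assert (la.feature_id, la.match_status) == ("F1", "full")

    def test_annotation_outside_every_window_kept_unlinked(self):
        ann = pm.AnnotationRecord(precursor_mz=340.2467, rt=600.0)
        [la] = pm.link_annotations_to_features([ann], self._setup())
        assert la.feature_id is None
        assert la.match_status == "unlinked"

    def test_shared_precursor_links_both_annotations(self):
        anns = [pm.AnnotationRecord(precursor_mz=340.2467, rt=289.0),
                pm.AnnotationRecord(precursor_mz=340.2468, rt=295.0)]
        linked = pm.link_annotations_to_features(anns, self._setup())
        assert [la.feature_id for la in linked] == ["F1", "F1"]

    def test_no_annotation_lost(self):
        rng = np.random.default_rng(17)
        anns = [pm.AnnotationRecord(precursor_mz=float(m), rt=float(r))
                for m, r in zip(rng.uniform(100, 1000, 25), rng.uniform(0, 700, 25))]
        linked = pm.link_annotations_to_features(anns, self._setup())
        assert len(linked) == len(anns)

    def test_ppm_tolerance_respected(self):
        ann = pm.AnnotationRecord(precursor_mz=340.2467 * (1 + 8e-6), rt=289.0)
        [strict] = pm.link_annotations_to_features([ann], self._setup(), ppm_tolerance=5.0)
        [loose] = pm.link_annotations_to_features([ann], self._setup(), ppm_tolerance=10.0)
        assert strict.match_status == "unlinked"
        assert loose.match_status == "full"


class TestMsiTally:
    def _linked(self, levels, comp="exo"):
        out = []
        for lvl in levels:
            source = {2: "spectral_db", 3: "compound_db"}.get(lvl, "none")
            rec = pm.AnnotationRecord(precursor_mz=100.0, rt=50.0, msi_level=lvl,
                                      source=source, condition=("", comp, "pos"))
            out.append(pm.LinkedAnnotation(rec, feature_id="F1", match_status="full"))
        return out

    def test_level_counts(self):
        tally = pm.tally_msi_levels(self._linked([2] * 3 + [3] * 5 + [4] * 2))
        row = tally.loc["exo_pos"]
        assert (row["total"], row["msi2"], row["msi3"], row["msi45"]) == (10, 3, 5, 2)

    def test_empty_input_all_zero(self):
        tally = pm.tally_msi_levels([])
        assert tally.empty

    def test_differential_join(self):
        tally = pm.tally_msi_levels(self._linked([2, 3]),
                                    selections={"SM": {"F1"}, "PP": set()})
        assert tally.loc["exo_pos", "n_differential_SM"] == 2
        assert tally.loc["exo_pos", "n_differential_PP"] == 0

    def test_msi_level_source_consistency_enforced(self):
        with pytest.raises(ValidationError):
            pm.AnnotationRecord(precursor_mz=100.0, rt=1.0, msi_level=2, source="none")


class TestSuspectScreen:
    def test_structure_match_shared_compound(self):
        fuco = "CC1(C)CC(O)CC(C)(C)C1=C=CC(C)=CC=CC(C)=CC=CC=C(C)C=CC=C(C)C(=O)CC2(O)CC(O)CC2(C)C"
        rec = pm.AnnotationRecord(precursor_mz=681.4, rt=536.0, name="all-trans-fucoxanthin",
                                  smiles=fuco, msi_level=3, source="compound_db")
        linked = [pm.LinkedAnnotation(rec, "F1", "full")]
        suspects = [pm.SuspectEntry(name="fucoxanthin", smiles=fuco, source_species="BOTH")]
        [match] = pm.screen_suspects(linked, suspects)
        assert match.level == "structure"
        assert match.source_species == "BOTH"

    def test_name_match_flagged_when_structures_differ(self):
        rec = pm.AnnotationRecord(precursor_mz=93.07, rt=282.0, name="Toluene",
                                  smiles="Cc1ccccc1")
        linked = [pm.LinkedAnnotation(rec, "F1", "full")]
        suspects = [pm.SuspectEntry(name="toluene", smiles="CCO", source_species="SM")]
        [match] = pm.screen_suspects(linked, suspects)
        assert match.level == "name"

    def test_no_overlap_gives_empty_result(self):
        rec = pm.AnnotationRecord(precursor_mz=100.0, rt=1.0, name="nothing", smiles="CCCC")
        linked = [pm.LinkedAnnotation(rec, None, "unlinked")]
        suspects = [pm.SuspectEntry(name="viburnitol", smiles="OC1CC(O)C(O)C(O)C1O")]
        assert pm.screen_suspects(linked, suspects) == []
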
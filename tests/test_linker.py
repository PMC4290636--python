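"""Identification/quantification linking, phospho filtering, MD-score, ANOVA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosmine import (
    LinkParams,
    PeptideID,
    QuantFeature,
    link,
    make_peptide_id,
    md_score,
    md_scores_by_sequence,
    parse_mod_string,
    read_ids_csv,
    read_quant_csv,
    summarize,
)
from phosmine.linker import LinkerConfigError, anova_p_value, group_ratio


def feature(mz=812.858, rt=23.9, charge=2, control=(100.0, 110.0, 90.0),
            treatment=(50.0, 55.0, 45.0), fid="F1"):
    return QuantFeature(
        feature_id=fid, mz=mz, rt=rt, charge=charge,
        abundances={
            "control": {f"c{i}": v for i, v in enumerate(control)},
            "treatment": {f"t{i}": v for i, v in enumerate(treatment)},
        },
    )


def pid(mz=812.86, rt=24.5, charge=2, score=40.0, sequence="DEHLSTLDAYRPK",
        mod="Phospho (Y): pY10", accession="ACC"):
    return make_peptide_id(sequence, mod, mz, charge, rt, score, accession)


class TestParseModString:
    def test_single_ptyr_site(self):
        sites = parse_mod_string("DEHLSTLDAYRPK", "Phospho (Y): pY10")
        assert sites == frozenset({("Y", 10)})

    def test_empty_mod_string(self):
        assert parse_mod_string("PEPTIDEK", "") == frozenset()

    def test_double_phospho(self):
        sites = parse_mod_string("ATRLSDEK", "2 Phospho (ST): pT2, pS5")
        assert sites == frozenset({("T", 2), ("S", 5)})

    def test_non_phospho_mods_ignored(self):
        sites = parse_mod_string(
            "AMYTK", "Oxidation (M); Phospho (Y): pY3")
        assert sites == frozenset({("Y", 3)})

    @pytest.mark.parametrize("mod", ["Phospho (Y): pY99", "Phospho (Y): pY1"])
    def test_inconsistent_position_raises(self, mod):
        with pytest.raises(ValueError):
            parse_mod_string("DEHLSTLDAYRPK", mod)

    def test_marked_sequence(self):
        assert pid().marked_sequence == "DEHLSTLDApYRPK"


class TestMdScore:
    @pytest.mark.parametrize(
        "scores, expected",
        [([39, 20], 19), ([30], 30), ([10, 10], 0), ([5, 40, 38], 2)],
    )
    def test_definition(self, scores, expected):
        assert md_score(scores) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            md_score([])

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_order_invariant_nonnegative(self, scores):
        forward = md_score(scores)
        assert forward >= 0
        assert md_score(list(reversed(scores))) == forward

    def test_grouping_by_sequence(self):
        ids = [
            pid(score=39, mod="Phospho (Y): pY10"),
            pid(score=20, mod="Phospho (S): pS5"),
            pid(score=30, sequence="AYK", mod="Phospho (Y): pY2"),
        ]
        out = md_scores_by_sequence(ids)
        assert out == {"DEHLSTLDAYRPK": 19, "AYK": 30}


class TestLink:
    def test_within_tolerance_links(self):
        result = link([pid()], [feature()])
        assert len(result.linked) == 1
        rec = result.linked[0]
        assert abs(rec.mz_diff) == pytest.approx(0.002, abs=1e-9)
        assert abs(rec.rt_diff) == pytest.approx(0.6, abs=1e-9)

    def test_no_features_all_unlinked(self):
        result = link([pid()], [])
        assert result.linked == [] and len(result.unlinked) == 1

    def test_score_threshold(self):
        result = link([pid(score=10)], [feature()])
        assert result.linked == [] and result.filtered_out == 1

    def test_phospho_filter_ptyr_only(self):
        ser = make_peptide_id("ASDFK", "Phospho (S): pS2", 812.86, 2,
                              24.5, 40.0)
        params = LinkParams(phospho_filter=frozenset(["pTyr"]))
        result = link([pid(), ser], [feature()], params)
        assert len(result.linked) == 1
        assert result.linked[0].id.sequence == "DEHLSTLDAYRPK"

    def test_charge_match_required_by_default(self):
        result = link([pid(charge=3)], [feature(charge=2)])
        assert result.linked == []
        relaxed = LinkParams(require_charge_match=False)
        assert len(link([pid(charge=3)], [feature(charge=2)], relaxed).linked) == 1

    def test_best_match_minimizes_mz_then_rt(self):
        far = feature(mz=812.90, fid="far")
        near = feature(mz=812.861, fid="near")
        result = link([pid()], [far, near])
        assert result.linked[0].feature.feature_id == "near"

    def test_keep_all_matches(self):
        feats = [feature(fid="a"), feature(mz=812.90, fid="b")]
        params = LinkParams(keep_all_matches=True)
        assert len(link([pid()], feats, params).linked) == 2

    def test_missing_condition_group_is_config_error(self):
        bad = QuantFeature("F", 812.86, 2, 24.0,
                           {"control": {"c1": 1.0}})
        with pytest.raises(LinkerConfigError):
            link([pid()], [bad])

    def test_infinity_ratio_when_treatment_zero(self):
        f = feature(treatment=(0.0, 0.0, 0.0))
        rec = link([pid()], [f]).linked[0]
        assert math.isinf(rec.group_ratio)

    @pytest.mark.parametrize("seed", range(3))
    def test_oracle_equivalence_random(self, seed):
        """Windowed linking equals exhaustive all-pairs assignment."""
        rng = np.random.default_rng(seed)
        params = LinkParams(mz_tol=0.5, rt_tol=5.0, min_score=0,
                            require_charge_match=False)
        feats = [feature(mz=float(rng.uniform(400, 420)),
                         rt=float(rng.uniform(10, 50)),
                         charge=int(rng.integers(2, 4)), fid=f"F{i}")
                 for i in range(100)]
        ids = [pid(mz=float(rng.uniform(400, 420)),
                   rt=float(rng.uniform(10, 50)),
                   charge=int(rng.integers(2, 4)), score=40)
               for _ in range(100)]
        got = link(ids, feats, params)
        for rec in got.linked:
            competitors = [
                f for f in feats
                if abs(rec.id.mz - f.mz) <= params.mz_tol
                and abs(rec.id.rt - f.rt) <= params.rt_tol
            ]
            best = min(competitors,
                       key=lambda f: (abs(rec.id.mz - f.mz),
                                      abs(rec.id.rt - f.rt), f.feature_id))
            assert rec.feature.feature_id == best.feature_id
        n_linkable = sum(
            any(abs(p.mz - f.mz) <= params.mz_tol
                and abs(p.rt - f.rt) <= params.rt_tol for f in feats)
            for p in ids)
        assert len(got.linked) == n_linkable

    def test_tolerance_and_score_monotonicity(self):
        rng = np.random.default_rng(4)
        feats = [feature(mz=float(rng.uniform(400, 410)),
                         rt=float(rng.uniform(10, 50)), fid=f"F{i}")
                 for i in range(50)]
        ids = [pid(mz=float(rng.uniform(400, 410)),
                   rt=float(rng.uniform(10, 50)),
                   score=float(rng.uniform(0, 60)))
               for _ in range(50)]

        def count(**kw):
            return len(link(ids, feats, LinkParams(
                require_charge_match=False, **kw)).linked)

        assert count(mz_tol=0.05, rt_tol=2) <= count(mz_tol=0.2, rt_tol=2)
        assert count(mz_tol=0.2, rt_tol=1) <= count(mz_tol=0.2, rt_tol=2)
        assert count(mz_tol=0.2, rt_tol=2, min_score=40) <= count(
            mz_tol=0.2, rt_tol=2, min_score=25)


class TestRatioAndAnova:
    def test_ratio_mean_over_mean(self):
        f = feature(control=(100, 110, 90), treatment=(50, 55, 45))
        assert group_ratio(f, "control", "treatment") == pytest.approx(2.0)

    def test_zero_over_zero_nan(self):
        f = feature(control=(0, 0, 0), treatment=(0, 0, 0))
        assert math.isnan(group_ratio(f, "control", "treatment"))

    def test_identical_groups_not_significant(self):
        f = feature(control=(100, 100, 100), treatment=(100, 100, 100))
        assert anova_p_value(f) > 0.05

    def test_planted_tenfold_difference_flagged(self):
        rng = np.random.default_rng(11)
        f = feature(control=tuple(1000 * rng.lognormal(0, 0.02, 3)),
                    treatment=tuple(100 * rng.lognormal(0, 0.02, 3)))
        assert anova_p_value(f) < 0.05

    def test_single_replicate_gives_no_p(self):
        f = feature(control=(100.0,), treatment=(50.0, 60.0))
        assert anova_p_value(f) is None

    def test_matches_scipy_directly(self):
        from scipy import stats
        f = feature()
        expected = stats.f_oneway(f.group_values("control"),
                                  f.group_values("treatment")).pvalue
        assert anova_p_value(f) == pytest.approx(expected)


class TestSummarize:
    def test_flags_and_sort(self):
        rng = np.random.default_rng(3)
        strong = link([pid()], [feature(
            control=tuple(1000 * rng.lognormal(0, 0.02, 3)),
            treatment=tuple(100 * rng.lognormal(0, 0.02, 3)))]).linked[0]
        flat = link([pid(mz=812.86)], [feature(
            control=(100, 101, 99), treatment=(100, 99, 101))]).linked[0]
        table = summarize([flat, strong], alpha=0.05)
        assert list(table["differential"]) == [True, False]  # ratio-desc sort
        assert table.loc[0, "ratio"] == pytest.approx(10.0, rel=0.1)
        assert "pY" in table.loc[0, "sequence"]

    def test_empty(self):
        assert len(summarize([])) == 0

    def test_missing_p_never_flagged(self):
        rec = link([pid()], [feature(control=(100.0,),
                                     treatment=(50.0,))]).linked[0]
        table = summarize([rec])
        assert not table["differential"].any()


class TestCsvReaders:
    def test_ids_roundtrip_and_invalid_row_excluded(self, tmp_path):
        path = tmp_path / "ids.csv"
        path.write_text(
            "prot_acc,pep_seq,pep_var_mod,pep_exp_mz,pep_exp_z,pep_rt,pep_score\n"
            "A1,DEHLSTLDAYRPK,Phospho (Y): pY10,812.858,2,24.1,39\n"
            "A2,PEPSIDEK,Phospho (S): pS99,500.1,2,11.0,30\n"  # bad position
            "A3,AYKR,,400.2,2,12.0,28\n"
        )
        ids = read_ids_csv(path)
        assert [i.accession for i in ids] == ["A1", "A3"]
        assert ids[0].phospho_sites == frozenset({("Y", 10)})

    def test_quant_reader_groups_by_condition(self, tmp_path):
        path = tmp_path / "quant.csv"
        path.write_text(
            "feature_id,mz,rt,charge,c1,c2,t1,t2\n"
            "F1,812.858,23.9,2,100,110,50,55\n"
        )
        feats = read_quant_csv(
            path, {"c1": "control", "c2": "control",
                   "t1": "treatment", "t2": "treatment"})
        assert len(feats) == 1
        assert feats[0].group_values("treatment") == [50.0, 55.0]

    def test_single_condition_map_rejected(self, tmp_path):
        path = tmp_path / "quant.csv"
        path.write_text("feature_id,mz,rt,charge,c1\nF1,500,10,2,5\n")
        with pytest.raises(LinkerConfigError):
            read_quant_csv(path, {"c1": "control"})
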
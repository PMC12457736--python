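import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from lipscan.lip import CLip, Lip, MLip
from lipscan.stats import (
    AA1,
    RESIDUE_GROUPS,
    ScoreTable,
    enrichment_factor,
    exposure_profile,
    mean_difference,
    proportion_ztest,
    read_dssp_masks,
    read_score_table,
    site_lip_report,
)
from lipscan.structure import SiteAnnotation, read_pdb
from lipscan.surface import ExposureClass


class TestEnrichment:
    def test_groups_partition_alphabet(self):
        union = set().union(*RESIDUE_GROUPS.values())
        assert union == set(AA1)
        assert sum(len(g) for g in RESIDUE_GROUPS.values()) == 20

    def test_identical_composition_gives_unit_ef(self):
        counts = {aa: 5 for aa in AA1}
        table = enrichment_factor(counts, {aa: 17 for aa in AA1})
        for e in list(table.per_aa.values()) + list(table.per_group.values()):
            assert e.ef == pytest.approx(1.0)

    def test_hand_computed_leucine_doubling(self):
        out_counts = {aa: 10 for aa in AA1}           # nu_out = 1/20 each
        in_counts = dict(out_counts, L=20, S=0)       # total stays 200
        table = enrichment_factor(in_counts, out_counts)
        assert table.per_aa["L"].ef == pytest.approx((20 / 200) / (10 / 200))
        assert table.per_aa["S"].ef == 0.0
        assert table.per_aa["A"].ef == pytest.approx(1.0)

    def test_absent_outside_region_flagged_not_infinite(self):
        out_counts = {aa: 1 for aa in AA1}
        out_counts["W"] = 0
        in_counts = {aa: 1 for aa in AA1}
        table = enrichment_factor(in_counts, out_counts)
        assert table.per_aa["W"].ef is None

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            enrichment_factor({aa: 0 for aa in AA1}, {aa: 1 for aa in AA1})

    @settings(max_examples=25, derandomize=True)
    @given(st_.lists(st_.integers(0, 50), min_size=20, max_size=20),
           st_.lists(st_.integers(0, 50), min_size=20, max_size=20))
    def test_group_ef_equals_member_frequency_combination(self, ins, outs):
        in_counts = dict(zip(AA1, ins))
        out_counts = dict(zip(AA1, outs))
        n_in, n_out = sum(ins), sum(outs)
        if n_in == 0 or n_out == 0:
            return
        table = enrichment_factor(in_counts, out_counts)
        for name, members in RESIDUE_GROUPS.items():
            nu_in = sum(in_counts[a] for a in members) / n_in
            nu_out = sum(out_counts[a] for a in members) / n_out
            entry = table.per_group[name]
            if nu_out == 0:
                assert entry.ef is None
            else:
                assert entry.ef == pytest.approx(nu_in / nu_out)


class TestProportionZtest:
    def test_equal_proportions_z_zero_p_one(self):
        z, p = proportion_ztest(10, 100, 30, 300)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest
        z, p = proportion_ztest(57, 301, 1907, 7668)
        z_ref, p_ref = proportions_ztest([57, 1907], [301, 7668])
        assert z == pytest.approx(z_ref)
        assert p == pytest.approx(p_ref)

    def test_site_full_lip_enrichment(self):
        # published SITE vs domain full-LIP counts
        _z, p = proportion_ztest(196, 301, 3983, 7668)
        assert p == pytest.approx(7e-6, rel=0.15)

    def test_buried_split(self):
        # published buried-in-full-LIP vs buried-outside counts
        _z, p = proportion_ztest(83, 196, 30, 104)
        assert p == pytest.approx(0.022, abs=0.002)

    def test_matches_monte_carlo_simulation(self):
        k1, n1, k2, n2 = 30, 150, 55, 400
        z, p = proportion_ztest(k1, n1, k2, n2)
        rng = np.random.default_rng(123)
        pooled = (k1 + k2) / (n1 + n2)
        draws = 400_000
        s1 = rng.binomial(n1, pooled, draws) / n1
        s2 = rng.binomial(n2, pooled, draws) / n2
        observed = abs(k1 / n1 - k2 / n2)
        p_mc = np.mean(np.abs(s1 - s2) >= observed - 1e-12)
        assert p == pytest.approx(p_mc, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ztest(1, 0, 1, 10)
        with pytest.raises(ValueError):
            proportion_ztest(11, 10, 1, 10)


class TestMeanDifference:
    def _table(self, values):
        return ScoreTable(scores={("A", i + 1, ""): v for i, v in enumerate(values)})

    @pytest.mark.filterwarnings("ignore:Precision loss")
    def test_constant_scores_zero_difference_and_d(self):
        table = self._table([2.5] * 50)
        mask = {("A", i, "") for i in range(1, 21)}
        report = mean_difference(table, mask)
        assert report.difference == 0.0
        assert report.cohens_d == 0.0

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(2024)
        inside = rng.normal(1.0, 1.0, 200)
        outside = rng.normal(0.0, 1.0, 800)
        table = self._table(list(inside) + list(outside))
        mask = {("A", i, "") for i in range(1, 201)}
        report = mean_difference(table, mask, element="mLIPs")
        se = math.sqrt(1 / 200 + 1 / 800)
        assert abs(report.difference - 1.0) < 3 * se
        assert report.cohens_d == pytest.approx(1.0, abs=0.15)
        assert report.p < 1e-10

    def test_complement_mask_negates_difference(self):
        rng = np.random.default_rng(5)
        table = self._table(list(rng.normal(0, 1, 60)))
        mask = {("A", i, "") for i in range(1, 25)}
        complement = set(table.scores) - mask
        r1 = mean_difference(table, mask)
        r2 = mean_difference(table, complement)
        assert r1.difference == pytest.approx(-r2.difference)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_point_biserial_t_identity(self, seed):
        rng = np.random.default_rng(seed)
        table = self._table(list(rng.normal(0, 1, 80) + rng.uniform(0, 2, 80)))
        mask = {("A", i, "") for i in range(1, 31)}
        r = mean_difference(table, mask)
        df = r.n_in + r.n_out - 2
        assert r.point_biserial ** 2 == pytest.approx(r.t ** 2 / (r.t ** 2 + df))

    def test_point_biserial_matches_scipy(self):
        from scipy.stats import pointbiserialr
        rng = np.random.default_rng(11)
        values = list(rng.normal(0, 1, 100))
        table = self._table(values)
        mask = {("A", i, "") for i in range(1, 41)}
        r = mean_difference(table, mask)
        binary = [1 if ("A", i + 1, "") in mask else 0 for i in range(100)]
        ref = pointbiserialr(binary, values)
        assert abs(r.point_biserial) == pytest.approx(abs(ref.statistic))
        assert r.p == pytest.approx(ref.pvalue)

    def test_empty_side_rejected(self):
        table = self._table([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            mean_difference(table, set(table.scores))

    def test_score_table_io(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text("chain\tresnum\ticode\tscore\nA\t1\t-\t0.5\nA\t2\t-\t-1.25\n")
        table = read_score_table(path)
        assert table.scores[("A", 1, "")] == 0.5
        assert table.scores[("A", 2, "")] == -1.25


def _lip(chain, span_nums, clip_nums):
    span = [(chain, n, "") for n in span_nums]
    mlip = MLip(chain_id=chain, span=span, mode="intra", partner=None, peak_pr=1.0)
    clip = CLip(parent=mlip, members=[((chain, n, ""), 5.0) for n in clip_nums])
    return Lip(mlip=mlip, clip=clip)


class TestSiteLipReport:
    @pytest.fixture()
    def structure(self, polar_bundle):
        return polar_bundle[0]

    def test_counts_match_brute_force(self, structure):
        lips = [_lip("A", range(4, 12), [1, 2, 15, 16]),
                _lip("A", range(27, 32), [9, 10, 24])]
        sites = [SiteAnnotation("AC1", [("A", n, "", "ALA", True)
                                        for n in (4, 5, 15, 33)])]
        report = site_lip_report(lips, sites, structure)
        rows = {r.element: r for r in report.rows}

        mlip = {("A", n, "") for n in list(range(4, 12)) + list(range(27, 32))}
        clip = {("A", n, "") for n in (1, 2, 15, 16, 9, 10, 24)}
        site = {("A", n, "") for n in (4, 5, 15, 33)}
        allk = set(structure.residue_keys())
        assert rows["mLIPs"].count_site == len(mlip & site)
        assert rows["cLIPs"].count_site == len(clip & site)
        assert rows["Full LIPs"].count_site == len((mlip | clip) & site)
        assert rows["NO LIPs"].count_all == len(allk - mlip - clip)
        assert rows["Full LIPs"].pct_site == pytest.approx(
            100 * len((mlip | clip) & site) / len(site))

    def test_full_lip_counts_each_residue_once(self, structure):
        lips = [_lip("A", range(4, 12), [5, 6, 15])]  # 5,6 also in the mLIP span
        report = site_lip_report(lips, [], structure)
        rows = {r.element: r for r in report.rows}
        assert rows["Full LIPs"].count_all == 8 + 1  # span ∪ {15}

    def test_no_sites_still_reports_domain_columns(self, structure):
        report = site_lip_report([_lip("A", range(4, 12), [])], [], structure)
        assert report.n_site == 0
        for row in report.rows:
            assert math.isnan(row.pct_site)
            assert row.count_all >= 0

    def test_all_sites_inside_one_mlip(self, structure):
        lips = [_lip("A", range(4, 12), [])]
        sites = [SiteAnnotation("AC1", [("A", n, "", "ALA", True)
                                        for n in range(4, 8)])]
        report = site_lip_report(lips, sites, structure)
        rows = {r.element: r for r in report.rows}
        assert rows["Full LIPs"].pct_site == 100.0

    def test_unresolvable_member_warned_and_skipped(self, structure):
        sites = [SiteAnnotation("AC1", [("A", 4, "", "ALA", True),
                                        ("Z", 999, "", "LIG", False)])]
        with pytest.warns(UserWarning, match="999"):
            report = site_lip_report([], sites, structure)
        assert report.n_site == 1


class TestExposureProfile:
    def _exposures(self, labels):
        out = {}
        for i, label in enumerate(labels):
            key = ("A", i + 1, "")
            rel = {"buried": 0.05, "intermediate": 0.2, "exposed": 0.6,
                   None: None}[label]
            out[key] = ExposureClass(residue_key=key, rel_exposure=rel, label=label)
        return out

    def test_all_buried(self):
        exposures = self._exposures(["buried"] * 5)
        prof = exposure_profile({"element": set(exposures)}, exposures)
        row = prof.rows[0]
        assert row.percentages == {"buried": 100.0, "intermediate": 0.0,
                                   "exposed": 0.0}

    def test_undefined_excluded_from_counts_but_in_total(self):
        exposures = self._exposures(["buried", "exposed", None, "intermediate"])
        prof = exposure_profile({"element": set(exposures)}, exposures)
        row = prof.rows[0]
        assert sum(row.counts.values()) == row.total - 1
        assert row.n_undefined == 1

    def test_random_mask_matches_brute_force(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(["buried", "intermediate", "exposed"], 60).tolist()
        exposures = self._exposures(labels)
        keys = sorted(exposures)
        mask = {k for k in keys if rng.random() < 0.4}
        prof = exposure_profile({"m": mask}, exposures)
        row = prof.rows[0]
        for label in ("buried", "intermediate", "exposed"):
            expected = sum(1 for k in mask if exposures[k].label == label)
            assert row.counts[label] == expected


def _dssp_line(index, resnum, chain, aa, ss):
    line = [" "] * 120
    line[:5] = f"{index:5d}"
    line[5:10] = f"{resnum:5d}"
    line[11] = chain
    line[13] = aa
    line[16] = ss
    line[34:38] = "   0"
    line[38:45] = "      0"
    line[46:50] = " 0.0"
    line[50:56] = "     0"
    line[57:61] = " 0.0"
    line[61:67] = "     0"
    line[68:72] = " 0.0"
    line[72:78] = "     0"
    line[79:83] = " 0.0"
    line[103:109] = "   0.0"
    line[109:115] = "   0.0"
    return "".join(line)


class TestDsspMasks:
    def test_masks_follow_strict_class_rules(self, tmp_path):
        rows = [(1, 1, "A", "A", "H"),   # alpha
                (2, 2, "A", "S", "G"),   # 3-10 helix: excluded
                (3, 3, "A", "L", "E"),   # beta strand
                (4, 4, "A", "K", "B"),   # beta bridge
                (5, 5, "A", "T", " "),   # coil (blank)
                (6, 6, "A", "N", "T"),   # turn: excluded
                (7, 7, "A", "D", "I")]   # pi helix: excluded
        text = "  #  RESIDUE AA STRUCTURE\n" + "\n".join(
            _dssp_line(*r) for r in rows) + "\n"
        path = tmp_path / "mini.dssp"
        path.write_text(text)
        masks = read_dssp_masks(path)
        assert masks["alpha"] == {("A", 1, "")}
        assert masks["beta"] == {("A", 3, ""), ("A", 4, "")}
        assert masks["coil"] == {("A", 5, "")}
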
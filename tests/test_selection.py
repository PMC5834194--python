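"""Candidate-selection rules: unit examples, oracles and invariances."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from lncswitch.selection import (
    FoldChangeRecord,
    SelectionThresholds,
    abundance_filter,
    cross_tissue_compare,
    direction_concordance,
    log2_fold_change,
    select_candidates,
    significance_aggregate,
    zero_denominator_check,
)

from conftest import make_annotation, make_dataset, make_gene

THR = SelectionThresholds()


def _rec(log2fc, direction, p=0.01, valid=True, dataset="d"):
    return FoldChangeRecord(
        gene_id="g",
        dataset=dataset,
        treatment_direction=direction,
        log2fc=log2fc,
        p_value=p,
        denominator_valid=valid,
    )


class TestAbundanceFilter:
    def _datasets(self, means):
        """One gene 'g' with the given per-dataset mean FPKM (constant)."""
        return [
            make_dataset(f"d{i}", "toward_synthetic", {"g": ([m, m], [m, m])})
            for i, m in enumerate(means)
        ]

    @pytest.mark.parametrize(
        "means,retained",
        [
            ((6.0, 2.0, 1.0), True),  # above threshold in one dataset suffices
            ((1.0, 1.0, 1.0), False),  # below in all -> removed
            ((5.0, 1.0, 1.0), True),  # "lower than 5" is strict
        ],
    )
    def test_default_all_policy(self, means, retained):
        kept = abundance_filter(self._datasets(means), THR)
        assert ("g" in kept) is retained

    def test_any_policy_removes_when_one_low(self):
        kept = abundance_filter(
            self._datasets((6.0, 2.0, 1.0)), THR.with_(abundance_policy="any")
        )
        assert "g" not in kept

    def test_empty_universe_errors(self):
        a = make_dataset("a", "toward_synthetic", {"g1": ([1], [1])})
        b = make_dataset("b", "toward_synthetic", {"g2": ([1], [1])})
        with pytest.raises(ValueError, match="universe"):
            abundance_filter([a, b], THR)


class TestLog2FoldChange:
    def test_simple_ratio(self):
        ds = make_dataset("d", "toward_synthetic", {"g": ([5, 5], [10, 10])})
        assert log2_fold_change(ds, "g").log2fc == pytest.approx(1.0)

    def test_identity(self):
        ds = make_dataset("d", "toward_synthetic", {"g": ([7, 7], [7, 7])})
        assert log2_fold_change(ds, "g").log2fc == pytest.approx(0.0)

    def test_zero_variance_both_groups_p_one(self):
        ds = make_dataset("d", "toward_synthetic", {"g": ([8, 8, 8, 8], [8, 8, 8, 8])})
        with pytest.warns(UserWarning, match="zero variance"):
            rec = log2_fold_change(ds, "g")
        assert rec.p_value == 1.0

    def test_absent_gene_raises(self):
        ds = make_dataset("d", "toward_synthetic", {"g": ([1], [1])})
        with pytest.raises(KeyError):
            log2_fold_change(ds, "nope")

    def test_single_sample_groups_have_undefined_p(self):
        ds = make_dataset("d", "toward_synthetic", {"g": ([5.0], [10.0])})
        assert math.isnan(log2_fold_change(ds, "g").p_value)

    def test_against_exhaustive_permutation_oracle(self):
        """Welch p should agree with exhaustive label permutation."""
        treated, control = (2.0, 4.0, 6.0), (1.0, 1.0, 1.0)
        ds = make_dataset("d", "toward_synthetic", {"g": (control, treated)})
        rec = log2_fold_change(ds, "g")
        assert rec.log2fc == pytest.approx(2.0)

        pooled = treated + control
        observed = abs(np.mean(treated) - np.mean(control))
        perms = [
            abs(np.mean(pick) - np.mean([v for i, v in enumerate(pooled) if i not in idx]))
            for idx in itertools.combinations(range(6), 3)
            for pick in [[pooled[i] for i in idx]]
        ]
        p_perm = sum(d >= observed - 1e-12 for d in perms) / len(perms)
        assert p_perm == pytest.approx(0.1)
        assert abs(rec.p_value - p_perm) < 0.05

    def test_rank_agreement_with_permutation_oracle(self, rng):
        """Across random genes, Welch p ranks like the permutation p."""
        welch, perm = [], []
        for _ in range(12):
            control = rng.lognormal(1, 0.4, size=4)
            treated = control * rng.uniform(0.5, 3.0) * rng.lognormal(0, 0.3, size=4)
            ds = make_dataset("d", "toward_synthetic", {"g": (control, treated)})
            welch.append(log2_fold_change(ds, "g").p_value)
            pooled = np.concatenate([treated, control])
            observed = abs(treated.mean() - control.mean())
            diffs = [
                abs(pooled[list(idx)].mean() - np.delete(pooled, list(idx)).mean())
                for idx in itertools.combinations(range(8), 4)
            ]
            perm.append(np.mean([d >= observed - 1e-12 for d in diffs]))
        rho = stats.spearmanr(welch, perm).statistic
        assert rho > 0.8


class TestZeroDenominator:
    @pytest.mark.parametrize(
        "control,invalid",
        [
            ((0, 0, 1, 2), True),  # 2/4 = 0.5 >= 0.5
            ((0, 1, 2, 3), False),  # 1/4 < 0.5
            ((0, 0, 0), True),  # all zero
        ],
    )
    def test_boundary(self, control, invalid):
        ds = make_dataset(
            "d", "toward_synthetic", {"g": (control, [1.0] * len(control))}
        )
        assert zero_denominator_check(ds, "g", "control", 0.5) is invalid

    def test_invalid_denominator_propagates_to_record(self):
        ds = make_dataset("d", "toward_synthetic", {"g": ((0, 0, 1, 2), (5, 6, 7, 8))})
        assert not log2_fold_change(ds, "g").denominator_valid


class TestDirectionConcordance:
    def test_synthetic_up_pattern(self):
        recs = [
            _rec(+0.6, "toward_synthetic"),
            _rec(-0.6, "toward_contractile"),
            _rec(-0.6, "toward_contractile"),
        ]
        assert direction_concordance(recs, THR) == "synthetic_up"

    def test_contractile_up_pattern(self):
        recs = [
            _rec(-0.6, "toward_synthetic"),
            _rec(+0.6, "toward_contractile"),
            _rec(+0.6, "toward_contractile"),
        ]
        assert direction_concordance(recs, THR) == "contractile_up"

    def test_one_violating_dataset_gives_none(self):
        recs = [
            _rec(+0.6, "toward_synthetic"),
            _rec(+0.6, "toward_contractile"),
            _rec(-0.6, "toward_contractile"),
        ]
        assert direction_concordance(recs, THR) == "none"

    def test_threshold_is_strict(self):
        recs = [
            _rec(+0.5, "toward_synthetic"),
            _rec(-0.6, "toward_contractile"),
            _rec(-0.6, "toward_contractile"),
        ]
        assert direction_concordance(recs, THR) == "none"

    def test_invalid_denominator_gives_none(self):
        recs = [
            _rec(+2.0, "toward_synthetic", valid=False),
            _rec(-2.0, "toward_contractile"),
        ]
        assert direction_concordance(recs, THR) == "none"

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            direction_concordance([], THR)


class TestSignificanceAggregate:
    @pytest.mark.parametrize(
        "p_values,expected",
        [
            ((0.05, 0.08, 0.20), True),  # 2 strict passes, all < 0.3
            ((0.05, 0.08, 0.35), False),  # loose bound violated
            ((0.05, 0.20, 0.25), False),  # only 1 strict pass
            ((0.05, 0.08, float("nan")), False),  # undefined p fails
        ],
    )
    def test_truth_table(self, p_values, expected):
        assert significance_aggregate(p_values, THR) is expected


# ---------------------------------------------------------------------------
# straight-line reference implementation of the full rule set


def _welch_p(treated, control):
    t = np.asarray(treated, float)
    c = np.asarray(control, float)
    if len(t) < 2 or len(c) < 2:
        return float("nan")
    vt, vc = t.var(ddof=1), c.var(ddof=1)
    if vt == 0 and vc == 0:
        return 1.0
    se2 = vt / len(t) + vc / len(c)
    tstat = (t.mean() - c.mean()) / math.sqrt(se2)
    df = se2**2 / (
        (vt / len(t)) ** 2 / (len(t) - 1) + (vc / len(c)) ** 2 / (len(c) - 1)
    )
    return 2.0 * stats.t.sf(abs(tstat), df)


def reference_selection(datasets, lnc_ids, thr):
    """Plain-loop re-implementation of the selection rules."""
    universe = set(lnc_ids)
    for ds in datasets:
        universe &= set(ds.fpkm.index)
    selected = {}
    for gene in sorted(universe):
        means = [
            float(np.mean(ds.fpkm.loc[gene, ds.control_samples + ds.treated_samples]))
            for ds in datasets
        ]
        if all(m < thr.min_avg_fpkm for m in means):
            continue
        fcs, ps, ok = {}, [], True
        for ds in datasets:
            control = ds.fpkm.loc[gene, ds.control_samples].to_numpy(float)
            treated = ds.fpkm.loc[gene, ds.treated_samples].to_numpy(float)
            zeros = np.sum(control == 0) / len(control)
            if zeros >= thr.zero_fraction:
                ok = False
                break
            fcs[ds.treatment_direction] = fcs.get(ds.treatment_direction, []) + [
                math.log2(treated.mean() / control.mean())
            ]
            ps.append(_welch_p(treated, control))
        if not ok:
            continue
        syn = all(f > thr.min_abs_log2fc for f in fcs.get("toward_synthetic", [])) and all(
            f < -thr.min_abs_log2fc for f in fcs.get("toward_contractile", [])
        )
        con = all(f < -thr.min_abs_log2fc for f in fcs.get("toward_synthetic", [])) and all(
            f > thr.min_abs_log2fc for f in fcs.get("toward_contractile", [])
        )
        if not (syn or con):
            continue
        strict = sum(p < thr.p_strict for p in ps)
        sig = (
            strict >= thr.n_strict
            and all(p < thr.p_loose for p in ps)
            and not any(math.isnan(p) for p in ps)
        )
        selected[gene] = ("synthetic_up" if syn else "contractile_up", sig)
    return selected


def _small_study(rng, n_genes=50, planted=None):
    """Three opposing smooth-muscle datasets over n_genes lncRNAs."""
    planted = planted or {}
    genes, annotation_genes = [], []
    data = {"pdgf": {}, "myocd": {}, "tgfb": {}}
    directions = {
        "pdgf": "toward_synthetic",
        "myocd": "toward_contractile",
        "tgfb": "toward_contractile",
    }
    pos = 1000
    for i in range(n_genes):
        gid = f"G{i:03d}"
        genes.append(gid)
        annotation_genes.append(make_gene(gid, "chr1", pos, pos + 500))
        pos += 10_000
        base = rng.lognormal(3, 0.7)
        cls = planted.get(gid)
        for name, direction in directions.items():
            if cls == "synthetic_up":
                eff = 1.0 if direction == "toward_synthetic" else -1.0
            elif cls == "contractile_up":
                eff = -1.0 if direction == "toward_synthetic" else 1.0
            elif cls == "zero_inflated":
                eff = 1.0 if direction == "toward_synthetic" else -1.0
            elif cls == "low":
                eff = 1.0
            else:
                eff = 0.0
            b = 0.5 if cls == "low" else base
            control = b * rng.lognormal(0, 0.1, size=4)
            treated = b * 2.0**eff * rng.lognormal(0, 0.1, size=4)
            if cls == "zero_inflated":
                control[:2] = 0.0
            data[name][gid] = (control, treated)
    datasets = [make_dataset(n, directions[n], data[n]) for n in directions]
    return datasets, make_annotation(*annotation_genes)


class TestSelectCandidates:
    PLANTED = {
        "G005": "synthetic_up",
        "G017": "synthetic_up",
        "G030": "synthetic_up",
        "G031": "contractile_up",
        "G040": "contractile_up",
        "G010": "zero_inflated",
        "G011": "low",
    }

    def test_matches_reference_implementation(self, rng):
        """Full selection equals the straight-line rule re-implementation."""
        datasets, annotation = _small_study(rng, planted=self.PLANTED)
        table = select_candidates(datasets, annotation, THR)
        got = {
            row.gene_id: (row.phenotype_class, bool(row.significant))
            for row in table.itertuples()
        }
        expected = reference_selection(datasets, set(annotation.genes), THR)
        assert got == expected

    def test_recovers_planted_classes(self, rng):
        datasets, annotation = _small_study(rng, planted=self.PLANTED)
        table = select_candidates(datasets, annotation, THR)
        classes = dict(zip(table["gene_id"], table["phenotype_class"]))
        assert classes.get("G005") == "synthetic_up"
        assert classes.get("G031") == "contractile_up"
        assert "G010" not in classes  # zero-inflated control group
        assert "G011" not in classes  # below abundance everywhere

    def test_all_noise_gives_empty_table(self, rng):
        datasets, annotation = _small_study(rng, planted={})
        assert len(select_candidates(datasets, annotation, THR)) == 0

    def test_sorted_descending_within_class(self, rng):
        datasets, annotation = _small_study(rng, planted=self.PLANTED)
        table = select_candidates(datasets, annotation, THR)
        for cls in ("synthetic_up", "contractile_up"):
            mags = table.loc[table.phenotype_class == cls, "mean_abs_log2fc"]
            assert list(mags) == sorted(mags, reverse=True)

    def test_requires_opposing_directions(self, rng):
        datasets, annotation = _small_study(rng)
        with pytest.raises(ValueError, match="opposing"):
            select_candidates(datasets[:1], annotation, THR)

    def test_invariant_under_within_group_sample_permutation(self, rng):
        datasets, annotation = _small_study(rng, n_genes=20, planted=self.PLANTED)
        table = select_candidates(datasets, annotation, THR)
        ds = datasets[0]
        shuffled = ds.fpkm[ds.control_samples[::-1] + ds.treated_samples[::-1]]
        shuffled.columns = ds.control_samples + ds.treated_samples
        ds.fpkm = shuffled
        table2 = select_candidates(datasets, annotation, THR)
        assert list(table["gene_id"]) == list(table2["gene_id"])

    def test_scaling_one_dataset_leaves_fold_changes_unchanged(self, rng):
        datasets, annotation = _small_study(rng, n_genes=20, planted=self.PLANTED)
        table = select_candidates(datasets, annotation, THR)
        datasets[1].fpkm = datasets[1].fpkm * 7.5
        table2 = select_candidates(datasets, annotation, THR)
        col = f"log2fc_{datasets[1].name}"
        assert np.allclose(table[col].to_numpy(), table2[col].to_numpy())

    def test_threshold_monotonicity(self, rng):
        """Raising the fold-change bar or tightening p never adds candidates."""
        datasets, annotation = _small_study(rng, planted=self.PLANTED)
        base = select_candidates(datasets, annotation, THR)
        stricter_fc = select_candidates(
            datasets, annotation, THR.with_(min_abs_log2fc=0.9)
        )
        assert set(stricter_fc["gene_id"]) <= set(base["gene_id"])
        stricter_p = select_candidates(datasets, annotation, THR.with_(p_strict=0.01))
        sig_base = set(base.loc[base.significant, "gene_id"])
        sig_strict = set(stricter_p.loc[stricter_p.significant, "gene_id"])
        assert sig_strict <= sig_base


class TestCrossTissue:
    def _candidates(self, rng, planted):
        datasets, annotation = _small_study(rng, planted=planted)
        table = select_candidates(datasets, annotation, THR)
        return table[table.significant].reset_index(drop=True)

    def _skeletal(self, gene_effects, rng):
        data = {}
        for gid, eff in gene_effects.items():
            base = 30.0
            data[gid] = (
                base * rng.lognormal(0, 0.05, size=4),
                base * 2.0**eff * rng.lognormal(0, 0.05, size=4),
            )
        return make_dataset("skel", "toward_differentiated", data)

    def test_direction_classification(self, rng):
        planted = {"G005": "synthetic_up", "G031": "contractile_up"}
        candidates = self._candidates(rng, planted)
        # synthetic_up => smooth toward-contractile change negative
        skel = self._skeletal({"G005": -1.0, "G031": -1.0}, rng)
        out = cross_tissue_compare(candidates, skel, THR)
        status = dict(zip(out["gene_id"], out["status"]))
        assert status["G005"] == "same_direction"
        assert status["G031"] == "opposite_direction"

    def test_below_threshold_not_comparable(self, rng):
        planted = {"G005": "synthetic_up"}
        candidates = self._candidates(rng, planted)
        skel = self._skeletal({"G005": -0.2}, rng)  # |log2fc| below 0.5
        out = cross_tissue_compare(candidates, skel, THR)
        assert out.loc[0, "status"] == "not_comparable"

    def test_absent_gene_not_comparable(self, rng):
        planted = {"G005": "synthetic_up"}
        candidates = self._candidates(rng, planted)
        skel = self._skeletal({"OTHER": -1.0}, rng)
        out = cross_tissue_compare(candidates, skel, THR)
        assert out.loc[0, "status"] == "not_comparable"

    def test_rejects_non_skeletal_dataset(self, rng):
        planted = {"G005": "synthetic_up"}
        candidates = self._candidates(rng, planted)
        smooth = make_dataset("x", "toward_synthetic", {"G005": ([1] * 4, [2] * 4)})
        with pytest.raises(ValueError):
            cross_tissue_compare(candidates, smooth, THR)
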
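"""Logit transform, BH, mixed-model fitting and the control-arm rule."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from splicescape import das as D
from splicescape.psi import compute_psi_from_junctions
from splicescape.simulate import (
    CohortSpec,
    build_event,
    generate_cohort,
    generate_splice_data,
    plan_effects,
)


class TestLogit:
    def test_midpoint_maps_to_zero(self):
        assert D.logit_transform(0.5) == pytest.approx(0.0)

    def test_boundary_remap(self):
        assert D.logit_transform(0.0) == pytest.approx(np.log(0.001 / 0.999), abs=1e-9)
        assert D.logit_transform(0.0) == pytest.approx(-6.9068, abs=1e-3)

    def test_antisymmetry(self):
        assert D.logit_transform(1.0) == pytest.approx(-D.logit_transform(0.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            D.logit_transform(1.1)

    def test_invalid_adjustment_rejected(self):
        with pytest.raises(ValueError):
            D.DasModelSpec(adjust=0.6)


def bh_oracle(p):
    """Independent brute-force step-up: adj_i = min over j with p_j >= p_i
    of m * p_j / rank_j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p[i] / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            D.benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_value_identity(self):
        np.testing.assert_allclose(D.benjamini_hochberg([0.04]), [0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(D.benjamini_hochberg([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            D.benjamini_hochberg([0.5, 1.5])

    def test_nan_excluded_from_family(self):
        out = D.benjamini_hochberg([0.02, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], bh_oracle([0.02, 0.04]))

    @given(st.lists(st.integers(0, 100), min_size=1, max_size=10))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, grid):
        p = np.array(grid) / 100.0
        np.testing.assert_allclose(D.benjamini_hochberg(p), bh_oracle(p), atol=1e-12)


def _sim_fits(n_per_arm, n_events, n_das, delta, seed, arm="EE", noise_sd=0.5):
    spec = CohortSpec(n_per_arm=n_per_arm, timepoints=("Pre", "P15M"), seed=seed)
    cohort = generate_cohort(spec)
    evs = [build_event(i)[0] for i in range(n_events)]
    sd = generate_splice_data(
        cohort, n_events, plan_effects(evs, n_das=n_das, delta=delta, arm=arm),
        noise_sd=noise_sd, seed=seed,
    )
    psi = compute_psi_from_junctions(sd.junctions, sd.events).psi
    return cohort, psi


class TestFitEvent:
    def test_constant_response_unfittable(self, small_cohort):
        psi = pd.Series(0.5, index=small_cohort["sample_id"])
        fr = D.fit_event(psi, small_cohort[small_cohort["arm"] == "EE"], "P15M")
        assert fr.status == "unfittable"

    def test_too_few_participants_unfittable(self, small_cohort):
        ee = small_cohort[small_cohort["arm"] == "EE"]
        keep = ee["pid"].isin(ee["pid"].unique()[:1])
        psi = pd.Series(
            np.linspace(0.3, 0.7, keep.sum()), index=ee.loc[keep, "sample_id"]
        )
        assert D.fit_event(psi, ee[keep], "P15M").status == "unfittable"

    def test_recovers_planted_coefficient(self):
        cohort, psi = _sim_fits(20, 12, 12, 1.5, seed=31)
        res = D.fit_arm_timepoint(psi, cohort, "EE", "P15M")
        assert res["status"].eq("ok").all()
        assert res["coef"].mean() == pytest.approx(1.5, rel=0.2)
        assert (res["fdr"] < 0.05).mean() >= 0.8

    def test_fdr_never_below_p(self):
        cohort, psi = _sim_fits(10, 10, 0, 0.0, seed=32)
        res = D.fit_arm_timepoint(psi, cohort, "EE", "P15M")
        ok = res.dropna(subset=["p"])
        assert (ok["fdr"] >= ok["p"] - 1e-12).all()

    def test_agrees_with_lmer_reference(self, tmp_path):
        """REML coefficient for one event matches lme4/lmerTest run on the
        same data (independent implementation route)."""
        cohort, psi = _sim_fits(20, 2, 2, 1.0, seed=33)
        ee = cohort[cohort["arm"] == "EE"].copy()
        y = D.logit_transform(psi.loc["ev00000", ee["sample_id"]].to_numpy())
        df = ee.assign(y=y, tp=(ee["Timepoint"] == "P15M").astype(int))
        data_path = tmp_path / "one_event.tsv"
        df.to_csv(data_path, sep="\t", index=False)
        rscript = textwrap.dedent(
            f"""
            suppressMessages(library(lmerTest))
            d <- read.delim("{data_path}")
            m <- lmer(y ~ tp + BMI + calculatedAge + pct_umi_dup + RIN
                        + factor(Batch) + factor(codedsiteid) + factor(Sex)
                        + (1|pid), data = d, REML = TRUE)
            co <- summary(m)$coefficients["tp", ]
            cat(co[["Estimate"]], co[["Pr(>|t|)"]], sep = "\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        coef_r, p_r = map(float, out.stdout.strip().split("\n"))
        fr = D.fit_event(psi.loc["ev00000"], ee, "P15M")
        assert fr.coef == pytest.approx(coef_r, abs=1e-3)
        # containment vs Satterthwaite df: compare p on the log scale
        assert np.log10(fr.p) == pytest.approx(np.log10(p_r), abs=0.5)


def _result_frame(rows):
    df = pd.DataFrame(rows)
    return df.set_index("event_id")


class TestControlRule:
    def _ex(self, fdr=0.01, direction=1):
        return _result_frame(
            [dict(event_id="e1", coef=1.0 * direction, p=fdr, fdr=fdr,
                  direction=direction, status="ok", arm="EE", timepoint="P15M",
                  track="junction", n_obs=40)]
        )

    def _ctl(self, fdr, direction):
        return _result_frame(
            [dict(event_id="e1", coef=1.0 * direction, p=fdr, fdr=fdr,
                  direction=direction, status="ok", arm="Control",
                  timepoint="P15M", track="junction", n_obs=40)]
        )

    def test_nonsignificant_control_keeps_das(self):
        out = D.call_das(self._ex(0.01), self._ctl(0.20, 1))
        assert out.loc["e1", "verdict"] == "DAS"

    def test_same_direction_significant_control_blocks(self):
        out = D.call_das(self._ex(0.01), self._ctl(0.01, 1))
        assert out.loc["e1", "verdict"] == "not-DAS"

    def test_opposite_direction_significant_control_passes(self):
        out = D.call_das(self._ex(0.01), self._ctl(0.01, -1))
        assert out.loc["e1", "verdict"] == "DAS"

    def test_untested_in_control_counts_nonsignificant(self):
        ctl = self._ctl(0.01, 1).drop(index="e1")
        out = D.call_das(self._ex(0.01), ctl if len(ctl) else None)
        assert out.loc["e1", "verdict"] == "DAS"

    def test_timepoint_mismatch_rejected(self):
        ctl = self._ctl(0.2, 1)
        ctl["timepoint"] = "P24H"
        with pytest.raises(ValueError):
            D.call_das(self._ex(0.01), ctl)

    def test_either_track_calls_the_event(self):
        long = pd.concat(
            [
                self._ex(0.01).reset_index().assign(verdict="DAS"),
                self._ex(0.50).reset_index().assign(track="isoform", verdict="not-DAS"),
            ]
        )
        cons = D.consolidate_verdicts(long)
        row = cons[cons["event_id"] == "e1"].iloc[0]
        assert row["verdict"] == "DAS" and row["source_tracks"] == "junction"


class TestDifferentialOmics:
    def test_recovers_planted_interaction(self):
        rng = np.random.default_rng(5)
        cohort = generate_cohort(CohortSpec(n_per_arm=15, timepoints=("Pre", "P15M"), seed=5))
        n = len(cohort)
        shift = ((cohort["arm"] == "EE") & (cohort["Timepoint"] == "P15M")).to_numpy()
        feats = {}
        for i in range(25):
            u = dict(zip(cohort["pid"].unique(), rng.normal(0, 0.3, cohort["pid"].nunique())))
            feats[f"f{i}"] = (
                rng.normal(0, 0.5, n)
                + cohort["pid"].map(u).to_numpy()
                + 1.0 * shift
            )
        mat = pd.DataFrame(feats, index=cohort["sample_id"]).T
        res = D.differential_omics(mat, cohort, "EE", "P15M")
        assert res["effect"].mean() == pytest.approx(1.0, rel=0.15)
        assert (res["fdr"] < 0.05).mean() > 0.8

    def test_zero_variance_feature_missing_p(self, small_cohort):
        mat = pd.DataFrame(
            {"const": np.zeros(len(small_cohort))}, index=small_cohort["sample_id"]
        ).T
        res = D.differential_omics(mat, small_cohort, "EE", "P15M")
        assert np.isnan(res.loc["const", "p"])

    def test_absent_cell_rejected(self, small_cohort):
        sub = small_cohort[small_cohort["Timepoint"] == "Pre"]
        mat = pd.DataFrame({"f": np.arange(len(sub))}, index=sub["sample_id"]).T
        with pytest.raises(ValueError):
            D.differential_omics(mat, sub, "EE", "P15M")


class TestMultilevelSummary:
    def test_set_arithmetic(self):
        genes = [f"g{i}" for i in range(10)]
        out = D.summarize_multilevel(
            genes,
            deg_genes={"g0", "g1", "g2", "g3"},
            das_genes={"g3", "g4", "g5"},
            phospho_genes={"g5", "g9"},
        )
        assert out == {"n_genes": 10, "DEG": 4, "DAS": 3, "phospho": 2, "any": 7}

    def test_empty_flags(self):
        out = D.summarize_multilevel(["a", "b"], set(), set(), set())
        assert out["any"] == 0

    def test_fully_flagged(self):
        genes = {"a", "b"}
        out = D.summarize_multilevel(genes, genes, genes, genes)
        assert out["any"] == len(genes)
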
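"""Differential methylation calling, overlaps and remodeling classification."""

import numpy as np
import pandas as pd
import pytest

from methlink.dmcpg import (
    call_dmcpgs,
    delta_beta,
    overlap_sets,
    remodeling_classification,
    remodeling_summary,
)
from methlink.stats import wilcoxon_rank_sum


def _two_group_beta(rng, n_probes, case_mu, ctrl_mu, n_case=10, n_ctrl=4, sd=0.05):
    case = np.clip(rng.normal(case_mu[:, None], sd, (n_probes, n_case)), 0.01, 0.99)
    ctrl = np.clip(rng.normal(ctrl_mu[:, None], sd, (n_probes, n_ctrl)), 0.01, 0.99)
    cols = [f"case{i}" for i in range(n_case)] + [f"ctrl{i}" for i in range(n_ctrl)]
    beta = pd.DataFrame(
        np.hstack([case, ctrl]),
        index=[f"cg{i:05d}" for i in range(n_probes)],
        columns=cols,
    )
    return beta, cols[:n_case], cols[n_case:]


class TestDeltaBeta:
    def test_group_mean_difference(self):
        beta = pd.DataFrame({"c1": [0.8], "c2": [0.8], "k1": [0.5], "k2": [0.5]})
        assert delta_beta(beta, ["c1", "c2"], ["k1", "k2"]).iloc[0] == pytest.approx(0.3)

    def test_missing_excluded_per_group(self):
        beta = pd.DataFrame({"c1": [0.9], "c2": [np.nan], "k1": [0.4], "k2": [0.6]})
        assert delta_beta(beta, ["c1", "c2"], ["k1", "k2"]).iloc[0] == pytest.approx(0.4)

    def test_empty_group_rejected(self):
        beta = pd.DataFrame({"a": [0.5]})
        with pytest.raises(ValueError):
            delta_beta(beta, [], ["a"])


class TestCallDMCpGs:
    def test_exact_threshold_not_called(self, rng):
        # |delta| must strictly exceed the threshold: a probe at exactly
        # 0.25 with a tiny q is not called
        beta = pd.DataFrame(
            {
                **{f"c{i}": [0.75] for i in range(10)},
                **{f"k{i}": [0.50] for i in range(4)},
            }
        )
        # add separating non-tied noise-free values via rank ordering
        beta.iloc[0, :10] = np.linspace(0.750, 0.7509, 10)
        beta.iloc[0, 10:] = np.linspace(0.500, 0.5009, 4)
        tab = call_dmcpgs(beta, [f"c{i}" for i in range(10)], [f"k{i}" for i in range(4)])
        assert tab["q"].iloc[0] < 0.05
        assert abs(tab["delta_beta"].iloc[0] - 0.25) < 1e-3
        assert not tab["called"].iloc[0]

    def test_identical_groups_zero_calls(self, rng):
        mu = rng.uniform(0.2, 0.8, 200)
        beta, case, ctrl = _two_group_beta(rng, 200, mu, mu)
        tab = call_dmcpgs(beta, case, ctrl)
        assert tab["called"].sum() == 0

    def test_antisymmetry_under_group_swap(self, rng):
        mu_c = rng.uniform(0.2, 0.8, 100)
        mu_k = np.clip(mu_c + rng.choice([0.0, 0.3], 100), 0.02, 0.98)
        beta, case, ctrl = _two_group_beta(rng, 100, mu_c, mu_k)
        fwd = call_dmcpgs(beta, case, ctrl)
        rev = call_dmcpgs(beta, ctrl, case)
        assert np.allclose(fwd["delta_beta"], -rev["delta_beta"])
        assert np.allclose(fwd["p"], rev["p"])
        assert np.allclose(fwd["q"], rev["q"])
        assert (fwd["called"] == rev["called"]).all()
        flipped = fwd.loc[fwd["called"], "direction"].map({"hyper": "hypo", "hypo": "hyper"})
        assert (rev.loc[fwd["called"], "direction"] == flipped).all()

    def test_vectorized_path_matches_scalar_kernel(self, rng):
        mu = rng.uniform(0.3, 0.7, 30)
        beta, case, ctrl = _two_group_beta(rng, 30, mu, mu)
        beta.iloc[0, 2] = np.nan  # force one probe onto the scalar path
        tab = call_dmcpgs(beta, case, ctrl)
        for probe in beta.index[:10]:
            x = beta.loc[probe, case].dropna().to_numpy()
            y = beta.loc[probe, ctrl].dropna().to_numpy()
            assert tab.loc[probe, "p"] == pytest.approx(
                wilcoxon_rank_sum(x, y).p_value, abs=1e-12
            )

    def test_planted_recovery_small(self, rng):
        mu = rng.uniform(0.2, 0.55, 2000)
        mu_case = mu.copy()
        planted = rng.choice(2000, 200, replace=False)
        mu_case[planted] += 0.3
        beta, case, ctrl = _two_group_beta(rng, 2000, mu_case, mu)
        tab = call_dmcpgs(beta, case, ctrl)
        called = set(np.flatnonzero(tab["called"].to_numpy()))
        tp = len(called & set(planted))
        assert tp / 200 >= 0.8
        assert (len(called) - tp) <= 0.1 * max(len(called), 1)


class TestOverlapSets:
    def _table(self, probes, called, direction="hyper"):
        return pd.DataFrame(
            {
                "called": [p in called for p in probes],
                "direction": direction,
            },
            index=probes,
        )

    def test_identical_sets_full_share(self):
        probes = list("abcde")
        t = self._table(probes, {"a", "b"})
        out = overlap_sets({"A": t, "B": t.copy()})
        row = out[(out.set_a == "A") & (out.set_b == "B")].iloc[0]
        assert row.share_of_a == 1.0 and row.n_concordant_direction == 2

    def test_disjoint_and_partial(self):
        probes = list("abcdef")
        tA = self._table(probes, {"a", "b", "c", "d"})
        tB = self._table(probes, {"c", "d", "e"})
        tC = self._table(probes, {"f"})
        out = overlap_sets({"A": tA, "B": tB, "C": tC})
        ab = out[(out.set_a == "A") & (out.set_b == "B")].iloc[0]
        assert ab.n_intersection == 2 and ab.share_of_a == 0.5
        ac = out[(out.set_a == "A") & (out.set_b == "C")].iloc[0]
        assert ac.n_intersection == 0
        assert out.attrs["n_common_all"] == 0

    def test_direction_discordance_counted(self):
        probes = list("ab")
        tA = self._table(probes, {"a", "b"}, direction="hyper")
        tB = self._table(probes, {"a", "b"}, direction="hypo")
        out = overlap_sets({"A": tA, "B": tB})
        assert out.iloc[0].n_concordant_direction == 0


class TestRemodeling:
    def _stage_pair(self, rng, n_sites, shift_ctrl, shift_case, sd=0.03):
        base = rng.uniform(0.5, 0.7, n_sites)
        sites = [f"cg{i}" for i in range(n_sites)]
        s1_cols = {f"{g}{i}_s1": None for g in ("c", "k") for i in range(4)}
        stage1 = pd.DataFrame(
            {
                **{f"c{i}_s1": np.clip(base + rng.normal(0, sd, n_sites), 0, 1) for i in range(4)},
                **{f"k{i}_s1": np.clip(base + rng.normal(0, sd, n_sites), 0, 1) for i in range(4)},
            },
            index=sites,
        )
        stage2 = pd.DataFrame(
            {
                **{
                    f"c{i}_s2": np.clip(base + shift_case + rng.normal(0, sd, n_sites), 0, 1)
                    for i in range(4)
                },
                **{
                    f"k{i}_s2": np.clip(base + shift_ctrl + rng.normal(0, sd, n_sites), 0, 1)
                    for i in range(4)
                },
            },
            index=sites,
        )
        groups = {
            "case": ([f"c{i}_s1" for i in range(4)], [f"c{i}_s2" for i in range(4)]),
            "control": ([f"k{i}_s1" for i in range(4)], [f"k{i}_s2" for i in range(4)]),
        }
        return sites, stage1, stage2, groups

    def test_identical_stages_all_unchanged(self, rng):
        sites, s1, _, groups = self._stage_pair(rng, 50, 0.0, 0.0)
        s2 = s1.rename(columns=lambda c: c.replace("_s1", "_s2"))
        out = remodeling_classification(sites, s1, s2, groups)
        summ = remodeling_summary(out, ["case", "control"])
        assert summ.loc["case", "fraction_unchanged"] == 1.0
        assert summ.loc["control", "fraction_unchanged"] == 1.0

    def test_control_only_demethylation_recovered(self, rng):
        sites, s1, s2, groups = self._stage_pair(rng, 60, shift_ctrl=-0.4, shift_case=0.0)
        out = remodeling_classification(sites, s1, s2, groups)
        summ = remodeling_summary(out, ["case", "control"])
        assert summ.loc["control", "fraction_changed"] >= 0.95
        assert summ.loc["case", "fraction_changed"] <= 0.05
        assert summ.loc["control", "fraction_demethylated"] >= 0.95

    def test_missing_stage_rejected(self, rng):
        sites, s1, s2, groups = self._stage_pair(rng, 10, -0.4, 0.0)
        groups["case"] = ([], groups["case"][1])
        with pytest.raises(ValueError, match="case"):
            remodeling_classification(sites, s1, s2, groups)


class TestNullBehaviour:
    def test_no_calls_on_null_array(self, small_study):
        """Planted-null stages produce zero DMCpG calls: with beta noise at
        0.05 the |delta| > 0.25 criterion is essentially unreachable."""
        from methlink.qc import filter_probes

        for stage in ("fibroblast", "iPSC", "neural_notDAn"):
            beta, _ = filter_probes(
                small_study.beta[stage],
                small_study.detection_p[stage],
                small_study.manifest,
            )
            tab = call_dmcpgs(
                beta,
                small_study.samples(stage, "PD"),
                small_study.samples(stage, "control"),
            )
            assert tab["called"].sum() == 0
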
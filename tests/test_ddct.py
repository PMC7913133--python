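import numpy as np
import pandas as pd
import pytest

from psykit.ddct import (
    CtTable,
    DdctResult,
    analyze,
    bootstrap_ci,
    collapse_technical,
    ddct_ratio,
    randomization_test,
)
from psykit.simulate import CtSimConfig, gen_ct_table


def small_table(rows) -> CtTable:
    return CtTable(data=pd.DataFrame(rows, columns=["gene", "group", "bio_rep", "tech_rep", "ct"]))


def flat_table(ct: float = 24.0, n_bio: int = 3) -> CtTable:
    rows = []
    for gene in ("PSY4", "actin-2"):
        for group in ("control", "treatment"):
            for bio in range(1, n_bio + 1):
                for tech in (1, 2):
                    rows.append((gene, group, bio, tech, ct))
    return small_table(rows)


class TestCollapse:
    def test_mean_of_two_technical_replicates(self):
        t = small_table(
            [
                ("g", "c", 1, 1, 20.0),
                ("g", "c", 1, 2, 20.4),
                ("actin-2", "c", 1, 1, 18.0),
            ]
        )
        collapsed = collapse_technical(t)
        got = collapsed[(collapsed["gene"] == "g")]["ct"].iloc[0]
        assert got == pytest.approx(20.2)

    def test_single_technical_replicate_is_identity(self):
        t = small_table([("g", "c", 1, 1, 31.5), ("actin-2", "c", 1, 1, 18.0)])
        assert collapse_technical(t)["ct"].tolist() == [18.0, 31.5]

    def test_equals_naive_groupby_on_random_tables(self):
        rng = np.random.default_rng(5)
        rows = []
        for gene in ("a", "b", "actin-2"):
            for group in ("c", "t"):
                for bio in (1, 2, 3):
                    for tech in (1, 2):
                        rows.append((gene, group, bio, tech, float(rng.normal(25, 3))))
        t = small_table(rows)
        collapsed = collapse_technical(t)
        for _, row in collapsed.iterrows():
            mask = (
                (t.data["gene"] == row["gene"])
                & (t.data["group"] == row["group"])
                & (t.data["bio_rep"] == row["bio_rep"])
            )
            assert row["ct"] == pytest.approx(t.data.loc[mask, "ct"].mean())


class TestDdctRatio:
    def test_null_case_ratio_one(self):
        res = ddct_ratio(flat_table(), "PSY4", "treatment")
        assert res.ddct == pytest.approx(0.0)
        assert res.ratio == pytest.approx(1.0)

    def test_one_cycle_shift_doubles_ratio(self):
        table = flat_table()
        data = table.data.copy()
        mask = (data["gene"] == "PSY4") & (data["group"] == "treatment")
        data.loc[mask, "ct"] -= 1.0
        res = ddct_ratio(CtTable(data=data), "PSY4", "treatment")
        assert res.ratio == pytest.approx(2.0)

    def test_efficiency_exponentiation(self):
        table = flat_table()
        data = table.data.copy()
        mask = (data["gene"] == "PSY4") & (data["group"] == "treatment")
        data.loc[mask, "ct"] -= 2.0
        res = ddct_ratio(CtTable(data=data), "PSY4", "treatment", efficiency=1.9)
        assert res.ratio == pytest.approx(1.9**2)

    def test_missing_reference_gene_rejected(self):
        with pytest.raises(ValueError, match="reference gene"):
            small_table([("g", "c", 1, 1, 20.0)])

    def test_parameter_recovery_within_5_percent(self):
        estimates = [
            ddct_ratio(
                gen_ct_table(CtSimConfig(seed=20_000 + s, genes={"PSY4": 4.0}))[0],
                "PSY4",
                "treatment",
            ).ratio
            for s in range(200)
        ]
        assert abs(np.mean(estimates) - 4.0) / 4.0 < 0.05


class TestRandomizationTest:
    def test_all_ct_identical_gives_p_one(self):
        p = randomization_test(flat_table(), "PSY4", "treatment", 200, seed=1)
        assert p == 1.0

    def test_add_one_lower_bound(self):
        table, _ = gen_ct_table(
            CtSimConfig(seed=3, genes={"PSY4": 16.0}, n_bio=8, noise_sd=0.05)
        )
        p = randomization_test(table, "PSY4", "treatment", 300, seed=2)
        assert p >= 1 / 301

    def test_reproducible_under_fixed_seed(self):
        table, _ = gen_ct_table(CtSimConfig(seed=6, genes={"PSY4": 2.0}))
        p1 = randomization_test(table, "PSY4", "treatment", 500, seed=9)
        p2 = randomization_test(table, "PSY4", "treatment", 500, seed=9)
        assert p1 == p2

    def test_needs_two_bio_reps_per_group(self):
        t = small_table(
            [
                ("g", "control", 1, 1, 20.0),
                ("g", "treatment", 1, 1, 20.0),
                ("actin-2", "control", 1, 1, 18.0),
                ("actin-2", "treatment", 1, 1, 18.0),
            ]
        )
        with pytest.raises(ValueError, match="biological replicates"):
            randomization_test(t, "g", "treatment", 100, seed=0)

    def test_strong_effect_detected(self):
        table, _ = gen_ct_table(
            CtSimConfig(seed=12, genes={"PSY4": 16.0}, n_bio=10, noise_sd=0.1)
        )
        p = randomization_test(table, "PSY4", "treatment", 1000, seed=4)
        assert p < 0.01


class TestBootstrapAndAnalyze:
    def test_ci_ordering_and_coverage_of_point_estimate(self):
        table, _ = gen_ct_table(CtSimConfig(seed=8, genes={"PSY4": 4.0}, n_bio=6))
        res = analyze(table, "PSY4", "treatment", seed=3)
        assert res.ci_low <= res.ci_high
        assert res.ci_low <= res.ratio <= res.ci_high
        assert 0 < res.p_value <= 1

    def test_result_invariants(self):
        with pytest.raises(ValueError):
            DdctResult(gene="g", ratio=1.0, ddct=0.0, p_value=0.0)
        with pytest.raises(ValueError):
            DdctResult(gene="g", ratio=1.0, ddct=0.0, ci_low=2.0, ci_high=1.0)

    def test_bootstrap_deterministic(self):
        table, _ = gen_ct_table(CtSimConfig(seed=9, genes={"PSY4": 3.0}))
        assert bootstrap_ci(table, "PSY4", "treatment", seed=11) == bootstrap_ci(
            table, "PSY4", "treatment", seed=11
        )

    def test_csv_round_trip(self, tmp_path):
        table, _ = gen_ct_table(CtSimConfig(seed=10, genes={"PSY4": 2.0}))
        path = tmp_path / "ct.csv"
        table.data.to_csv(path, index=False)
        back = CtTable.from_csv(path)
        res_a = ddct_ratio(table, "PSY4", "treatment")
        res_b = ddct_ratio(back, "PSY4", "treatment")
        assert res_a.ratio == pytest.approx(res_b.ratio)
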
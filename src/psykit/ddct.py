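"""Comparative-Ct (ddCt) relative expression with a randomization test.

Relative expression of a target gene between two groups is estimated by the
comparative threshold-cycle method: technical replicates are averaged,
dCt = Ct(target) - Ct(reference) is formed per biological replicate,
ddCt = mean dCt(treatment) - mean dCt(control), and the expression ratio is
``efficiency ** -ddCt`` (efficiency 2 = perfect doubling per cycle).

Inference follows the fixed-reallocation randomization approach popularized
by the REST software: group labels of whole biological replicates are
permuted jointly for target and reference gene, and a two-sided Monte Carlo
p-value with add-one correction is reported.  A percentile bootstrap over
biological replicates gives an interval for the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("gene", "group", "bio_rep", "tech_rep", "ct")


@dataclass
class CtTable:
    """Replicate-structured qPCR Ct measurements.

    ``data`` columns: gene, group, bio_rep, tech_rep, ct (cycles).
    """

    data: pd.DataFrame
    reference_gene: str = "actin-2"
    control_group: str = "control"

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing column(s): {missing}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if not np.isfinite(ct).all():
            raise ValueError("all Ct values must be finite")
        groups = self.data["group"].unique()
        for g in groups:
            sub = self.data[self.data["group"] == g]
            if self.reference_gene not in set(sub["gene"]):
                raise ValueError(
                    f"reference gene {self.reference_gene!r} absent from group {g!r}"
                )

    @classmethod
    def from_csv(
        cls,
        path,
        reference_gene: str = "actin-2",
        control_group: str = "control",
    ) -> "CtTable":
        return cls(
            data=pd.read_csv(path),
            reference_gene=reference_gene,
            control_group=control_group,
        )

    def genes(self) -> list[str]:
        return sorted(set(self.data["gene"]))


@dataclass(frozen=True)
class DdctResult:
    """Relative-expression estimate for one gene."""

    gene: str
    ratio: float
    ddct: float
    p_value: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")
        if (
            self.ci_low is not None
            and self.ci_high is not None
            and self.ci_low > self.ci_high
        ):
            raise ValueError("ci_low must be <= ci_high")


def collapse_technical(table: CtTable) -> pd.DataFrame:
    """Arithmetic mean Ct over technical replicates.

    Returns one row per (gene, group, bio_rep); biological replicates stay
    intact as the units of downstream analysis.
    """
    return (
        table.data.groupby(["gene", "group", "bio_rep"], as_index=False)["ct"]
        .mean()
        .sort_values(["gene", "group", "bio_rep"], kind="stable")
        .reset_index(drop=True)
    )


def _dct_per_bio_rep(
    collapsed: pd.DataFrame, table: CtTable, gene: str, group: str
) -> np.ndarray:
    """dCt = Ct(target) - Ct(reference) per biological replicate of a group."""
    sub = collapsed[collapsed["group"] == group]
    target = sub[sub["gene"] == gene].set_index("bio_rep")["ct"]
    ref = sub[sub["gene"] == table.reference_gene].set_index("bio_rep")["ct"]
    if target.empty:
        raise ValueError(f"gene {gene!r} absent from group {group!r}")
    common = target.index.intersection(ref.index)
    if len(common) == 0:
        raise ValueError(
            f"no biological replicate has both {gene!r} and the reference "
            f"gene in group {group!r}"
        )
    return (target.loc[common] - ref.loc[common]).to_numpy(dtype=float)


def ddct_ratio(
    table: CtTable,
    gene: str,
    treatment_group: str,
    efficiency: float = 2.0,
) -> DdctResult:
    """Point estimate of relative expression (no inference fields filled)."""
    collapsed = collapse_technical(table)
    dct_treat = _dct_per_bio_rep(collapsed, table, gene, treatment_group)
    dct_ctrl = _dct_per_bio_rep(collapsed, table, gene, table.control_group)
    ddct = float(dct_treat.mean() - dct_ctrl.mean())
    return DdctResult(gene=gene, ratio=float(efficiency**-ddct), ddct=ddct)


def randomization_test(
    table: CtTable,
    gene: str,
    treatment_group: str,
    n_permutations: int = 2000,
    seed: int = 0,
    efficiency: float = 2.0,
) -> float:
    """Two-sided randomization p-value for ddCt != 0.

    Biological replicates (with their paired target/reference Ct means) are
    reallocated between the two groups uniformly at random; the p-value is
    ``(1 + #{|ddCt*| >= |ddCt_obs|}) / (1 + n_permutations)``, deterministic
    for a given seed.  At least two biological replicates per group are
    required.
    """
    collapsed = collapse_technical(table)
    dct_treat = _dct_per_bio_rep(collapsed, table, gene, treatment_group)
    dct_ctrl = _dct_per_bio_rep(collapsed, table, gene, table.control_group)
    n_t, n_c = len(dct_treat), len(dct_ctrl)
    if n_t < 2 or n_c < 2:
        raise ValueError("randomization test needs >= 2 biological replicates per group")
    obs = abs(dct_treat.mean() - dct_ctrl.mean())
    pooled = np.concatenate([dct_treat, dct_ctrl])
    rng = np.random.default_rng(seed)
    # one permutation per row, vectorized
    idx = np.argsort(rng.random((n_permutations, n_t + n_c)), axis=1)
    permuted = pooled[idx]
    stat = np.abs(
        permuted[:, :n_t].mean(axis=1) - permuted[:, n_t:].mean(axis=1)
    )
    exceed = int(np.sum(stat >= obs - 1e-12))
    return (1 + exceed) / (1 + n_permutations)


def bootstrap_ci(
    table: CtTable,
    gene: str,
    treatment_group: str,
    n_boot: int = 1000,
    seed: int = 0,
    efficiency: float = 2.0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the expression ratio.

    Biological replicates are resampled with replacement within each group.
    """
    collapsed = collapse_technical(table)
    dct_treat = _dct_per_bio_rep(collapsed, table, gene, treatment_group)
    dct_ctrl = _dct_per_bio_rep(collapsed, table, gene, table.control_group)
    rng = np.random.default_rng(seed)
    t_idx = rng.integers(0, len(dct_treat), size=(n_boot, len(dct_treat)))
    c_idx = rng.integers(0, len(dct_ctrl), size=(n_boot, len(dct_ctrl)))
    ddct = dct_treat[t_idx].mean(axis=1) - dct_ctrl[c_idx].mean(axis=1)
    ratios = efficiency**-ddct
    alpha = (1 - level) / 2
    lo, hi = np.quantile(ratios, [alpha, 1 - alpha])
    return float(lo), float(hi)


def analyze(
    table: CtTable,
    gene: str,
    treatment_group: str,
    efficiency: float = 2.0,
    n_permutations: int = 2000,
    n_boot: int = 1000,
    seed: int = 0,
) -> DdctResult:
    """Full ddCt analysis: point estimate, randomization p-value, bootstrap CI."""
    point = ddct_ratio(table, gene, treatment_group, efficiency)
    p = randomization_test(
        table, gene, treatment_group, n_permutations, seed, efficiency
    )
    lo, hi = bootstrap_ci(table, gene, treatment_group, n_boot, seed, efficiency)
    return DdctResult(
        gene=gene,
        ratio=point.ratio,
        ddct=point.ddct,
        p_value=p,
        ci_low=lo,
        ci_high=hi,
        n_permutations=n_permutations,
        seed=seed,
    )
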
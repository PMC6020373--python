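"""Five-hypothesis colocalization from summary statistics.

Per-SNP evidence is the Wakefield approximate Bayes factor computed from
(beta, se); the locus-level posterior over the five standard hypotheses —
no association (H0), trait-1-only (H1), trait-2-only (H2), two distinct
causal variants (H3), one shared causal variant (H4) — follows from
summing single-causal-variant configurations with priors p1, p2, p12.
Only SNPs present in both series are analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .containers import BloodtxError

#: Conventional prior effect SDs for the ABF.
PRIOR_SD_QUANT = 0.15
PRIOR_SD_CC = 0.2


@dataclass
class SummarySeries:
    """Per-SNP association summary statistics at one locus.

    ``table`` columns: snp_id, position, beta, se, n.  ``trait_type`` is
    "quant" or "cc" (case-control, betas on the log-odds scale).
    """

    table: pd.DataFrame
    trait_type: str = "quant"
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quant", "cc"):
            raise BloodtxError(f"unknown trait type {self.trait_type!r}")
        bad = self.table.loc[self.table["se"] <= 0, "snp_id"]
        if len(bad):
            raise BloodtxError(f"non-positive se for SNPs {list(bad[:5])}")
        if not np.isfinite(self.table[["beta", "se"]].to_numpy()).all():
            raise BloodtxError("non-finite beta/se in summary series")

    @property
    def default_prior_sd(self) -> float:
        return PRIOR_SD_CC if self.trait_type == "cc" else PRIOR_SD_QUANT


@dataclass
class ColocResult:
    pp: np.ndarray                 # PP0..PP4
    n_snps: int
    priors: tuple[float, float, float]
    snp_h4: pd.Series = field(default=None)   # per-SNP shared-variant posterior

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    @property
    def pp3(self) -> float:
        return float(self.pp[3])

    def as_dict(self) -> dict:
        out = {f"PP{i}": float(self.pp[i]) for i in range(5)}
        out["n_snps"] = self.n_snps
        out["p1"], out["p2"], out["p12"] = self.priors
        return out


def approximate_bayes_factors(series: SummarySeries,
                              prior_sd: float | None = None) -> pd.Series:
    """Per-SNP log approximate Bayes factor (Wakefield).

    log ABF = 0.5 [ log(V/(V+W)) + z^2 W/(V+W) ],  W = prior_sd^2.

    For quantitative traits V = se^2.  For case-control traits V is the
    effective-sample-size proxy 1/(n phi (1-phi)) (phi = case fraction,
    default 0.5) and only z = beta/se enters, so results depend on the
    summary statistics solely through z and n — jointly rescaling betas
    and ses leaves the posterior unchanged.
    """
    W = (series.default_prior_sd if prior_sd is None else prior_sd) ** 2
    se2 = series.table["se"].to_numpy(dtype=float) ** 2
    z2 = (series.table["beta"].to_numpy(dtype=float) / np.sqrt(se2)) ** 2
    if series.trait_type == "cc":
        phi = 0.5 if series.case_fraction is None else series.case_fraction
        V = 1.0 / (series.table["n"].to_numpy(dtype=float) * phi * (1 - phi))
    else:
        V = se2
    labf = 0.5 * (np.log(V / (V + W)) + z2 * W / (V + W))
    return pd.Series(labf, index=series.table["snp_id"].to_numpy(), name="log_abf")


def colocalize(series_1: SummarySeries, series_2: SummarySeries,
               p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
               prior_sd_1: float | None = None,
               prior_sd_2: float | None = None) -> ColocResult:
    """Posterior over H0..H4 for two traits at a shared locus."""
    l1 = approximate_bayes_factors(series_1, prior_sd_1)
    l2 = approximate_bayes_factors(series_2, prior_sd_2)
    shared = l1.index.intersection(l2.index)
    if len(shared) == 0:
        raise BloodtxError("no shared SNPs between the two series")
    a = l1.loc[shared].to_numpy()
    b = l2.loc[shared].to_numpy()

    lsum_a = logsumexp(a)
    lsum_b = logsumexp(b)
    lsum_ab = logsumexp(a + b)
    # H3: sum over i != j of ABF1_i * ABF2_j (log-space difference)
    with np.errstate(over="ignore"):
        l_h3_sum = lsum_a + lsum_b + np.log1p(
            -np.exp(np.clip(lsum_ab - (lsum_a + lsum_b), -np.inf, -1e-16)))

    lh = np.array([
        0.0,
        np.log(p1) + lsum_a,
        np.log(p2) + lsum_b,
        np.log(p1) + np.log(p2) + l_h3_sum,
        np.log(p12) + lsum_ab,
    ])
    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    snp_h4 = pd.Series(np.exp(a + b - lsum_ab), index=shared, name="snp_pp_h4")
    return ColocResult(pp=pp, n_snps=len(shared), priors=(p1, p2, p12),
                       snp_h4=snp_h4)
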
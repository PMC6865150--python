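"""Confirmation-stage statistics for the targeted capture panel.

The confirmation experiment measures per-DMR read depth (a proxy for
methylation) in an independent cohort. The stage runs:

1. *vertical normalization* — every sample column is rescaled so the
   cumulative panel depth is equal across samples (factor ``T_bar / T_s``
   with ``T_bar`` the mean of the per-sample totals, which conserves the
   grand total);
2. a mixed-effects analysis of variance ``y = mu + tau_tissue + b_dmr + eps``
   with a random DMR intercept (capture efficiency and methylation
   variability differ between regions), fitted by REML via statsmodels
   MixedLM; the tissue effect is tested with a likelihood-ratio test of the
   ML fits with and without the tissue term against chi-square with
   (n_tissues - 1) df;
3. three post-hoc pairwise Welch t-tests on the pooled per-DMR-per-sample
   normalized depths, Holm-Bonferroni corrected.

Panels may carry non-differential control rows (``is_control``): they take
part in normalization but are excluded from the tissue statistics.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .difftest import welch_arrays
from .windows import SampleMeta, ValidationError

log = logging.getLogger(__name__)

TOTAL_RTOL = 1e-9


@dataclass
class PanelDepthMatrix:
    """Selected DMRs (rows) x confirmation samples (columns) read depths."""

    dmr_ids: List[str]
    samples: List[SampleMeta]
    depth: np.ndarray                  # (n_dmrs, n_samples), non-negative
    normalized: bool = False
    is_control: np.ndarray | None = None  # bool per row; controls anchor normalization

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.depth.shape != (len(self.dmr_ids), len(self.samples)):
            raise ValidationError(
                f"depth shape {self.depth.shape} does not match "
                f"{len(self.dmr_ids)} DMRs x {len(self.samples)} samples"
            )
        if (self.depth < 0).any():
            raise ValidationError("panel depths must be non-negative")
        if self.is_control is None:
            self.is_control = np.zeros(len(self.dmr_ids), dtype=bool)
        else:
            self.is_control = np.asarray(self.is_control, dtype=bool)

    @property
    def tissues(self) -> List[str]:
        return sorted({s.tissue for s in self.samples})

    def columns_for(self, tissue: str) -> List[int]:
        return [i for i, s in enumerate(self.samples) if s.tissue == tissue]

    def dmr_rows(self) -> np.ndarray:
        """Depths of the non-control rows."""
        return self.depth[~self.is_control]


@dataclass
class PairwiseResult:
    pair: Tuple[str, str]
    t: float
    df: float
    p_raw: float
    p_holm: float = 1.0


@dataclass
class ConfirmationReport:
    tissue_means: Dict[str, float]
    anova_stat: float
    anova_p: float
    sigma_dmr: float
    sigma_resid: float
    pairwise: List[PairwiseResult] = field(default_factory=list)
    converged: bool = True
    boundary_sigma_dmr: bool = False

    def to_dict(self) -> Dict:
        return {
            "tissue_means": self.tissue_means,
            "anova_stat": self.anova_stat,
            "anova_p": self.anova_p,
            "sigma_dmr": self.sigma_dmr,
            "sigma_resid": self.sigma_resid,
            "converged": self.converged,
            "boundary_sigma_dmr": self.boundary_sigma_dmr,
            "pairwise": [
                {
                    "pair": list(r.pair),
                    "t": r.t,
                    "df": r.df,
                    "p_raw": r.p_raw,
                    "p_holm": r.p_holm,
                }
                for r in self.pairwise
            ],
        }


def vertical_normalize(panel: PanelDepthMatrix) -> PanelDepthMatrix:
    """Equalize every sample's cumulative panel depth at the mean total.

    Each column s is multiplied by ``f_s = T_bar / T_s`` where ``T_s`` is the
    column total and ``T_bar`` the mean of the totals, so the grand total is
    conserved and reapplication is the identity.
    """
    totals = panel.depth.sum(axis=0)
    if (totals <= 0).any():
        offender = panel.samples[int(np.flatnonzero(totals <= 0)[0])].sample_id
        raise ValidationError(f"sample {offender!r} has zero total panel depth")
    factors = totals.mean() / totals
    return PanelDepthMatrix(
        dmr_ids=list(panel.dmr_ids),
        samples=list(panel.samples),
        depth=panel.depth * factors[None, :],
        normalized=True,
        is_control=panel.is_control.copy(),
    )


def _long_frame(panel: PanelDepthMatrix, log1p: bool = False) -> pd.DataFrame:
    """Non-control rows in long form: one row per (DMR, sample)."""
    keep = ~panel.is_control
    ids = [d for d, k in zip(panel.dmr_ids, keep) if k]
    depth = panel.depth[keep]
    if log1p:
        depth = np.log1p(depth)
    records = {
        "y": depth.ravel(),
        "dmr": np.repeat(ids, len(panel.samples)),
        "tissue": np.tile([s.tissue for s in panel.samples], len(ids)),
    }
    return pd.DataFrame(records)


def fit_mixed_anova(panel: PanelDepthMatrix, log1p: bool = False) -> ConfirmationReport:
    """REML mixed model with random DMR intercept; ML LRT for the tissue effect.

    Depths are analyzed on the raw scale by default (``log1p=True`` applies a
    variance-stabilizing log(1 + y) transform first). Degenerate all-constant
    input short-circuits to a null report; a variance-component estimate at
    the zero boundary is reported with ``boundary_sigma_dmr=True``.
    """
    import statsmodels.formula.api as smf

    if not panel.normalized:
        raise ValidationError("panel must be vertically normalized before fitting")
    tissues = panel.tissues
    if len(tissues) < 2:
        raise ValidationError("need >= 2 tissues")
    n_dmr = int((~panel.is_control).sum())
    if n_dmr < 2:
        raise ValidationError("need >= 2 non-control DMRs")
    for t in tissues:
        if len(panel.columns_for(t)) < 2:
            raise ValidationError(f"need >= 2 samples in tissue {t}")

    data = _long_frame(panel, log1p=log1p)
    tissue_means = {t: float(data.loc[data["tissue"] == t, "y"].mean()) for t in tissues}

    if np.ptp(data["y"].to_numpy()) == 0.0:
        return ConfirmationReport(
            tissue_means=tissue_means, anova_stat=0.0, anova_p=1.0,
            sigma_dmr=0.0, sigma_resid=0.0,
        )

    def _fit(formula: str, reml_flag: bool):
        """MixedLM fit with optimizer fallbacks; boundary fits are accepted.

        A random-effect variance shrinking to zero routinely trips the
        convergence flag although the parameters are at the boundary optimum;
        such fits are kept (the caller reports ``boundary_sigma_dmr``).
        """
        model = smf.mixedlm(formula, data, groups=data["dmr"])
        last = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in (None, "lbfgs", "powell"):
                try:
                    res = model.fit(reml=reml_flag, **({"method": method} if method else {}))
                except Exception:
                    continue
                last = res
                if res.converged:
                    return res
        if last is not None and np.isfinite(last.llf):
            at_boundary = float(last.cov_re.iloc[0, 0]) < 1e-8 * max(float(last.scale), 1.0)
            if at_boundary:
                return last
            raise ValidationError(
                f"mixed-model fit did not converge for {formula!r} "
                f"(final log-likelihood {last.llf:.4g})"
            )
        raise ValidationError(f"mixed-model fit failed for {formula!r}")

    reml = _fit("y ~ C(tissue)", True)
    full = _fit("y ~ C(tissue)", False)
    null = _fit("y ~ 1", False)
    sigma_dmr = float(np.sqrt(max(reml.cov_re.iloc[0, 0], 0.0)))
    sigma_resid = float(np.sqrt(reml.scale))
    boundary = sigma_dmr < 1e-6 * max(sigma_resid, 1.0)
    if boundary:
        log.warning("fit_mixed_anova: random DMR variance at zero boundary")
    lrt = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(stats.chi2.sf(lrt, df=len(tissues) - 1))
    return ConfirmationReport(
        tissue_means=tissue_means,
        anova_stat=float(lrt),
        anova_p=p,
        sigma_dmr=sigma_dmr,
        sigma_resid=sigma_resid,
        converged=True,
        boundary_sigma_dmr=bool(boundary),
    )


def pairwise_welch_posthoc(
    panel: PanelDepthMatrix, log1p: bool = False, per_sample_means: bool = False
) -> List[PairwiseResult]:
    """Welch t-tests for every tissue pair on pooled normalized depths.

    The observation unit is one DMR in one sample (``per_sample_means=True``
    collapses each sample to its mean over the panel first). Holm-adjusted
    p-values are filled in across the three pairs.
    """
    if not panel.normalized:
        raise ValidationError("panel must be vertically normalized before testing")
    tissues = panel.tissues
    depth = panel.dmr_rows()
    if log1p:
        depth = np.log1p(depth)
    pooled: Dict[str, np.ndarray] = {}
    for t in tissues:
        cols = panel.columns_for(t)
        block = depth[:, cols]
        pooled[t] = block.mean(axis=0) if per_sample_means else block.ravel()
    results: List[PairwiseResult] = []
    for a, b in combinations(tissues, 2):
        if len(pooled[a]) < 2 or len(pooled[b]) < 2:
            raise ValidationError(f"tissue pair ({a}, {b}) has < 2 observations")
        t, df, p = welch_arrays(pooled[a][None, :], pooled[b][None, :])
        results.append(PairwiseResult(pair=(a, b), t=float(t[0]), df=float(df[0]), p_raw=float(p[0])))
    adj = holm_bonferroni(np.array([r.p_raw for r in results]))
    for r, pa in zip(results, adj):
        r.p_holm = float(pa)
    return results


def holm_bonferroni(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment, returned in the original order.

    Sorted ascending, ``adj_(i) = max_{j<=i} min(1, (m - j + 1) * p_(j))``.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def confirm_panel(panel: PanelDepthMatrix, log1p: bool = False) -> ConfirmationReport:
    """Full confirmation stage: normalize, mixed ANOVA, post-hoc pairwise."""
    normed = vertical_normalize(panel)
    report = fit_mixed_anova(normed, log1p=log1p)
    report.pairwise = pairwise_welch_posthoc(normed, log1p=log1p)
    return report


# ---------------------------------------------------------------------------
# Synthetic additive-model panels (oracle generator for the fitter)
# ---------------------------------------------------------------------------

def simulate_additive_panel(
    n_dmrs: int,
    samples_per_tissue: Dict[str, int],
    tissue_means: Dict[str, float],
    sigma_dmr: float,
    sigma_resid: float,
    rng: np.random.Generator,
) -> PanelDepthMatrix:
    """Draw a panel directly from the additive mixed model.

    ``y_{d,s} = mu_tissue(s) + b_d + eps`` with ``b_d ~ N(0, sigma_dmr^2)``
    and ``eps ~ N(0, sigma_resid^2)``. Used to check parameter recovery of
    :func:`fit_mixed_anova` against known truth. Depths are shifted to be
    non-negative; the panel is flagged normalized (the model is already on
    the analysis scale).
    """
    metas: List[SampleMeta] = []
    for tissue in sorted(samples_per_tissue):
        for i in range(samples_per_tissue[tissue]):
            metas.append(
                SampleMeta(f"{tissue}_{i + 1}", tissue, cohort="confirmation", library_size=1)
            )
    b = rng.normal(0.0, sigma_dmr, size=n_dmrs)
    mu = np.array([tissue_means[s.tissue] for s in metas])
    y = mu[None, :] + b[:, None] + rng.normal(0.0, sigma_resid, size=(n_dmrs, len(metas)))
    y -= min(0.0, y.min())  # keep depths non-negative without changing contrasts
    return PanelDepthMatrix(
        dmr_ids=[f"dmr_{i + 1}" for i in range(n_dmrs)],
        samples=metas,
        depth=y,
        normalized=True,
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_panel_tsv(panel: PanelDepthMatrix, path) -> None:
    frame = pd.DataFrame(panel.depth, index=panel.dmr_ids, columns=[s.sample_id for s in panel.samples])
    frame.insert(0, "is_control", panel.is_control.astype(int))
    frame.index.name = "dmr_id"
    frame.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


def read_panel_tsv(path, samples: Sequence[SampleMeta]) -> PanelDepthMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    is_control = None
    if "is_control" in frame.columns:
        is_control = frame.pop("is_control").to_numpy(dtype=bool)
    samples = list(samples)
    frame = frame[[s.sample_id for s in samples]]
    return PanelDepthMatrix(
        dmr_ids=[str(i) for i in frame.index],
        samples=samples,
        depth=frame.to_numpy(dtype=np.float64),
        is_control=is_control,
    )


def write_report_json(report: ConfirmationReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def tissue_quartiles(panel: PanelDepthMatrix) -> pd.DataFrame:
    """Per-tissue quartile summary of pooled normalized depths (box-plot data)."""
    rows = []
    depth = panel.dmr_rows()
    for t in panel.tissues:
        vals = depth[:, panel.columns_for(t)].ravel()
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"tissue": t, "q1": q1, "median": q2, "q3": q3,
                     "mean": vals.mean(), "n": vals.size})
    return pd.DataFrame(rows)
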
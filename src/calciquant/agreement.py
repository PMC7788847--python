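"""Method-agreement statistics for two paired series of area measurements.

Three complementary views, as used when validating an automated measurement
against a human reference:

* **Spearman's rho** — monotone association between the two series. The
  p-value uses the t approximation ``t = rho * sqrt((n-2)/(1-rho^2))`` for
  n >= 10 and the exact permutation distribution below that.
* **Lin's concordance correlation coefficient (CCC)** — penalises both poor
  correlation and systematic location/scale shifts:
  ``ccc = 2 cov(x,y) / (var(x) + var(y) + (mean(x)-mean(y))^2)`` with
  population (1/n) moments, per Lin's original estimator. The 95% CI is
  computed on the Fisher z scale with Lin's asymptotic standard error and
  back-transformed; a bootstrap CI is available as an alternative.
* **Bland-Altman** — bias (mean of the differences d = x - y), the sample
  standard deviation of d, and 95% limits of agreement bias ± 1.96 sd.

`validate` assembles all three plus plot data (scatter with identity line,
Bland-Altman with bias/limit lines) exportable as CSV and rendered PNGs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .grids import BinaryMask  # noqa: F401  (re-exported context type)

__all__ = [
    "PairedSeries",
    "AgreementResult",
    "ConstantSeriesError",
    "spearman",
    "lin_ccc",
    "bland_altman",
    "BlandAltmanResult",
    "validate",
]

_Z95 = 1.96  # the conventional limits-of-agreement multiplier


class ConstantSeriesError(ValueError):
    """A correlation statistic is undefined because one series is constant."""


@dataclass(frozen=True)
class PairedSeries:
    """Two paired measurement series (e.g. mm² lesion areas by two methods)."""

    labels: tuple[str, ...]
    x: np.ndarray  # method A
    y: np.ndarray  # method B

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        labels = tuple(str(l) for l in self.labels)
        if not (len(x) == len(y) == len(labels)):
            raise ValueError("labels, x and y must have equal length")
        if len(x) < 3:
            raise ValueError("paired series needs at least 3 observations")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("all paired values must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_arrays(cls, x, y, labels=None) -> "PairedSeries":
        x = np.asarray(x, dtype=np.float64)
        if labels is None:
            labels = [str(i) for i in range(len(x))]
        return cls(labels=tuple(labels), x=x, y=np.asarray(y, dtype=np.float64))

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    means: np.ndarray  # per-point (x+y)/2
    diffs: np.ndarray  # per-point x - y
    direction: str = "x - y"  # sign convention, recorded explicitly

    def __iter__(self):
        yield self.bias
        yield self.loa_low
        yield self.loa_high
        yield self.sd_diff


@dataclass(frozen=True)
class AgreementResult:
    """All three statistics for one pair of measurement methods."""

    n: int
    spearman_rho: float
    spearman_p: float
    ccc: float
    ccc_ci_low: float
    ccc_ci_high: float
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    alpha: float = 0.05
    difference_direction: str = "x - y"

    @property
    def significant(self) -> bool:
        return self.spearman_p <= self.alpha

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def _check_not_constant(series: PairedSeries) -> None:
    if np.ptp(series.x) == 0 or np.ptp(series.y) == 0:
        raise ConstantSeriesError("correlation undefined for a constant series")


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for small n (enumeration over all n!)."""
    n = len(rx)
    sx = (rx - rx.mean()) / rx.std()
    sy = (ry - ry.mean()) / ry.std()
    count = 0
    total = 0
    # rho for a permutation pi is mean(sx * sy[pi]); enumerate in chunks
    perms = itertools.permutations(range(n))
    chunk = []
    target = abs(rho_obs) - 1e-12
    for p in perms:
        chunk.append(p)
        if len(chunk) == 40320:
            idx = np.array(chunk)
            rhos = (sx[None, :] * sy[idx]).mean(axis=1)
            count += int((np.abs(rhos) >= target).sum())
            total += len(chunk)
            chunk = []
    if chunk:
        idx = np.array(chunk)
        rhos = (sx[None, :] * sy[idx]).mean(axis=1)
        count += int((np.abs(rhos) >= target).sum())
        total += len(chunk)
    return count / total


def spearman(series: PairedSeries) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties get average ranks. p is exact (full permutation distribution) for
    n < 10 and the usual t approximation for n >= 10.
    """
    _check_not_constant(series)
    rx = stats.rankdata(series.x)
    ry = stats.rankdata(series.y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = series.n
    if n < 10:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def _ccc_point(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(ccc, pearson r, location-shift u) with population moments."""
    mx, my = x.mean(), y.mean()
    sx2 = ((x - mx) ** 2).mean()
    sy2 = ((y - my) ** 2).mean()
    sxy = ((x - mx) * (y - my)).mean()
    ccc = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    r = sxy / np.sqrt(sx2 * sy2)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    return float(ccc), float(r), float(u)


def lin_ccc(
    series: PairedSeries,
    alpha: float = 0.05,
    ci: str = "fisher",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient with a confidence interval.

    ``ci="fisher"`` (default) uses Lin's asymptotic variance on the Fisher z
    scale; ``ci="bootstrap"`` uses the percentile bootstrap with ``n_boot``
    resamples.
    """
    _check_not_constant(series)
    x, y = series.x, series.y
    n = series.n
    ccc, r, u = _ccc_point(x, y)
    if ci == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        vals = []
        for row in idx:
            xb, yb = x[row], y[row]
            if np.ptp(xb) == 0 or np.ptp(yb) == 0:
                continue
            vals.append(_ccc_point(xb, yb)[0])
        lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
        return ccc, float(lo), float(hi)
    if ci != "fisher":
        raise ValueError("ci must be 'fisher' or 'bootstrap'")
    if abs(ccc) >= 1.0 or r == 0.0:
        return ccc, ccc, ccc  # perfectly concordant/degenerate: zero-width CI
    # Lin's asymptotic SE of z = atanh(ccc)
    c2 = ccc * ccc
    r2 = r * r
    var_z = (
        (1 - r2) * c2 / ((1 - c2) * r2)
        + 4 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - c2) ** 2)
        - 2 * ccc**4 * u**4 / (r2 * (1 - c2) ** 2)
    ) / (n - 2)
    se_z = float(np.sqrt(max(var_z, 0.0)))
    z = np.arctanh(ccc)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - zcrit * se_z), np.tanh(z + zcrit * se_z)
    return ccc, float(lo), float(hi)


def bland_altman(series: PairedSeries) -> BlandAltmanResult:
    """Bias and 95% limits of agreement for the differences d = x - y.

    ``sd_diff`` uses the sample (n-1) standard deviation; the limits are
    ``bias ± 1.96 sd_diff``. Per-point means and differences are returned
    for plotting.
    """
    d = series.x - series.y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - _Z95 * sd,
        loa_high=bias + _Z95 * sd,
        sd_diff=sd,
        means=(series.x + series.y) / 2.0,
        diffs=d,
    )


def validate(
    series: PairedSeries,
    alpha: float = 0.05,
    out_dir: str | Path | None = None,
) -> AgreementResult:
    """Run all three agreement analyses; optionally write plots and plot data.

    When ``out_dir`` is given, writes ``scatter.png`` (method A vs method B
    with the identity line), ``bland_altman.png`` (differences vs means with
    bias and limit lines), ``plot_data.csv`` with the plotted coordinates,
    and ``agreement.json`` with the full result.
    """
    rho, p = spearman(series)
    ccc, ci_lo, ci_hi = lin_ccc(series, alpha=alpha)
    ba = bland_altman(series)
    result = AgreementResult(
        n=series.n,
        spearman_rho=rho,
        spearman_p=p,
        ccc=ccc,
        ccc_ci_low=ci_lo,
        ccc_ci_high=ci_hi,
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        sd_diff=ba.sd_diff,
        alpha=alpha,
        difference_direction=ba.direction,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "label": series.labels,
                "x": series.x,
                "y": series.y,
                "mean": ba.means,
                "diff": ba.diffs,
            }
        ).to_csv(out / "plot_data.csv", index=False)
        (out / "agreement.json").write_text(result.to_json())
        _render_plots(series, ba, result, out)
    return result


def _render_plots(series: PairedSeries, ba: BlandAltmanResult, res: AgreementResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(series.x, series.y, s=18, color="tab:blue")
    lims = [min(series.x.min(), series.y.min()), max(series.x.max(), series.y.max())]
    ax.plot(lims, lims, color="green", lw=1, label="identity")
    ax.set_xlabel("method A (mm²)")
    ax.set_ylabel("method B (mm²)")
    ax.set_title(f"rho={res.spearman_rho:.2f}, CCC={res.ccc:.2f} "
                 f"[{res.ccc_ci_low:.2f}, {res.ccc_ci_high:.2f}]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "scatter.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5.0, 4.0))
    ax.scatter(ba.means, ba.diffs, s=18, color="tab:blue")
    ax.axhline(ba.bias, color="purple", lw=1.2, label=f"bias {ba.bias:.2f}")
    ax.axhline(ba.loa_low, color="red", lw=1, ls="--", label="95% limits")
    ax.axhline(ba.loa_high, color="red", lw=1, ls="--")
    ax.set_xlabel("mean of methods (mm²)")
    ax.set_ylabel(f"difference, {ba.direction} (mm²)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "bland_altman.png", dpi=120)
    plt.close(fig)
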
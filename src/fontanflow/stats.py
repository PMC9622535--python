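"""Method-agreement statistics: linear regression and Bland-Altman.

Used to compare two sets of paired metric values, e.g. steady vs.
pulsatile runs of the same cases, or simulation vs. reference
measurements.  The Bland-Altman difference direction is fixed as
first argument minus second.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InvalidInputError


@dataclass
class AgreementResult:
    """Regression + Bland-Altman summary of two paired metric sets."""

    slope: Optional[float]
    intercept: Optional[float]
    r: Optional[float]
    p_value: Optional[float]
    bias: float
    sd_of_differences: float
    loa_lower: float
    loa_upper: float
    n: int
    means: np.ndarray
    differences: np.ndarray

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept, "r": self.r,
            "p_value": self.p_value, "bias": self.bias,
            "sd_of_differences": self.sd_of_differences,
            "limits_of_agreement": [self.loa_lower, self.loa_upper],
            "n": self.n,
        }


def linear_regression(x: Sequence[float], y: Sequence[float]):
    """Ordinary least squares of y on x.

    Returns ``(slope, intercept, r, p_value)`` with r the Pearson
    correlation and the p-value from the two-sided t-test on the slope.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise InvalidInputError("regression p-value needs >= 3 points")
    if np.ptp(x) == 0:
        raise InvalidInputError("degenerate regression: x is constant")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), \
        float(res.pvalue)


def bland_altman(a: Sequence[float], b: Sequence[float]) -> AgreementResult:
    """Bland-Altman agreement of two paired sequences.

    Differences ``d = a - b``; bias = mean(d); sd = sample SD (n-1
    denominator); limits of agreement = bias +/- 1.96 sd.  Per-pair
    (mean, difference) points are returned for plotting.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("sequences must be equal-length and 1-D")
    if len(a) < 2:
        raise InvalidInputError("Bland-Altman needs >= 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    means = 0.5 * (a + b)
    slope = intercept = r = p = None
    if len(a) >= 3 and np.ptp(a) > 0:
        try:
            slope, intercept, r, p = linear_regression(a, b)
        except InvalidInputError:
            pass
    return AgreementResult(
        slope=slope, intercept=intercept, r=r, p_value=p,
        bias=bias, sd_of_differences=sd,
        loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd,
        n=len(a), means=means, differences=d)


def compare(a: Sequence[float], b: Sequence[float]) -> AgreementResult:
    """Full agreement analysis (regression of b on a + Bland-Altman)."""
    result = bland_altman(a, b)
    return result


def agreement_plots(result: AgreementResult, a, b, path_prefix: str,
                    label_a: str = "A", label_b: str = "B") -> list:
    """Write scatter+regression and Bland-Altman plots as PNG files."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(a, b, s=25, color="tab:blue")
    if result.slope is not None:
        xs = np.linspace(a.min(), a.max(), 10)
        ax.plot(xs, result.slope * xs + result.intercept, "k-",
                label=f"y = {result.slope:.3g} x + {result.intercept:.3g}\n"
                      f"r = {result.r:.3f}")
        ax.legend(fontsize=8)
    ax.set_xlabel(label_a)
    ax.set_ylabel(label_b)
    fig.tight_layout()
    p1 = f"{path_prefix}_regression.png"
    fig.savefig(p1, dpi=120)
    plt.close(fig)
    paths.append(p1)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(result.means, result.differences, s=25, color="tab:orange")
    for yv, style in ((result.bias, "k-"), (result.loa_lower, "k--"),
                      (result.loa_upper, "k--")):
        ax.axhline(yv, linestyle=style[1:], color="k", linewidth=1)
    ax.set_xlabel(f"mean of {label_a} and {label_b}")
    ax.set_ylabel(f"{label_a} - {label_b}")
    fig.tight_layout()
    p2 = f"{path_prefix}_bland_altman.png"
    fig.savefig(p2, dpi=120)
    plt.close(fig)
    paths.append(p2)
    return paths
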
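"""Branch-model likelihood-ratio test on supplied log-likelihoods.

The null model fits a single dN/dS ratio (omega) across the tree; the
alternative frees omega on a foreground branch set. With the alternative
nesting the null, 2 * (l1 - l0) is asymptotically chi-square with df equal
to the number of extra omega parameters (df=1 for one extra ratio). The
maximum-likelihood fits themselves come from codeml; this module only does
the test arithmetic and result-file scraping.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

from scipy.stats import chi2

from .errors import ParseError, ValidationError

NESTING_TOL = 1e-6


@dataclass(frozen=True)
class BranchModelFit:
    """One fitted branch model: H0 (one omega) or H1 (two omegas)."""

    label: str
    log_likelihood: float
    omegas: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.omegas):
            raise ValidationError(f"{self.label}: negative omega")


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float


def likelihood_ratio_test(
    null: BranchModelFit, alt: BranchModelFit, df: int = 1
) -> LRTResult:
    """2*(l1 - l0) against the upper chi-square tail with ``df`` degrees.

    The alternative must nest the null: l1 >= l0 - 1e-6, else the upstream
    optimization failed and an error is raised. p is never rounded here;
    presentation layers round to 4 significant decimals.
    """
    if df < 1:
        raise ValidationError("df must be a positive integer")
    diff = alt.log_likelihood - null.log_likelihood
    if diff < -NESTING_TOL:
        raise ValidationError(
            f"alternative log-likelihood {alt.log_likelihood} below null "
            f"{null.log_likelihood}: failed optimization upstream"
        )
    if null.omegas and alt.omegas:
        extra = len(alt.omegas) - len(null.omegas)
        if extra != df:
            warnings.warn(
                f"df={df} but the models differ by {extra} omega parameter(s)"
            )
    statistic = max(0.0, 2.0 * diff)
    p_value = float(chi2.sf(statistic, df))
    return LRTResult(statistic=statistic, df=df, p_value=p_value)


_LNL_RE = re.compile(r"lnL\s*(?:\([^)]*\))?\s*[:=]\s*(-?\d+(?:\.\d+)?)")
_OMEGA_LINE_RE = re.compile(
    r"(?:^|\b)(?:omega|w)\s*\(dN/dS\)\s*(?:for branches)?\s*[:=]\s*(.+)$",
    re.IGNORECASE,
)
_FLOAT_RE = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?")


def read_codeml_lnl(path: str | Path, label: str = "fit") -> BranchModelFit:
    """Scrape lnL and omega values from a codeml main-result text file.

    Recognizes one-ratio lines like ``omega (dN/dS) =  0.03395`` and
    branch-model lines like ``w (dN/dS) for branches:  0.02200 0.03820``.
    """
    text = Path(path).read_text()
    m = _LNL_RE.search(text)
    if m is None:
        raise ParseError(f"{path}: no lnL line found")
    lnl = float(m.group(1))
    omegas: tuple[float, ...] = ()
    for line in text.splitlines():
        om = _OMEGA_LINE_RE.search(line)
        if om:
            values = tuple(float(v) for v in _FLOAT_RE.findall(om.group(1)))
            if values:
                omegas = values
    return BranchModelFit(label=label, log_likelihood=lnl, omegas=omegas)


def format_result(result: LRTResult) -> str:
    """Presentation form: statistic to 4 decimals, p to 4 significant decimals."""
    return (
        f"2*delta_lnL = {result.statistic:.4f}, df = {result.df}, "
        f"p = {result.p_value:.4g}"
    )
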
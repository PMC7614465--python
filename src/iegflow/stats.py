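"""Shared statistical kernels.

Thin, contract-explicit wrappers around classical tests: Student t
(one-sample, two-sample pooled or Welch, paired) and simple ordinary
least squares with the overall F test.  Every result is returned as a
:class:`TestResult` that serializes into the pipeline's CSV/JSON
summaries.  p-values are two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float
    n: tuple
    method: str
    seed: Optional[int] = None
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
            "n": list(self.n),
            "method": self.method,
            "seed": self.seed,
            "degenerate": self.degenerate,
            **self.extra,
        }


def _finalize(t: float, df: float, n, method: str) -> TestResult:
    if not np.isfinite(t):
        # zero-variance sample with a nonzero mean difference
        return TestResult(float(np.sign(t) * np.inf) if t else 0.0,
                          0.0 if t else 1.0, df, n, method, degenerate=True)
    p = 2.0 * sps.t.sf(abs(t), df) if df > 0 else np.nan
    return TestResult(float(t), float(p), float(df), n, method)


def t_test_one_sample(x, mu0: float = 0.0) -> TestResult:
    """Two-sided one-sample Student t of mean(x) against ``mu0``."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("one-sample t-test needs n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        d = x.mean() - mu0
        return TestResult(
            0.0 if d == 0 else float(np.sign(d) * np.inf),
            1.0 if d == 0 else 0.0, float(n - 1), (n,),
            "t_one_sample", degenerate=True,
        )
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    return _finalize(t, n - 1, (n,), "t_one_sample")


def t_test_two_sample(x, y, equal_var: bool = True) -> TestResult:
    """Two-sided two-sample Student t (pooled variance by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("two-sample t-test needs n >= 2 per sample")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        d = x.mean() - y.mean()
        return TestResult(
            0.0 if d == 0 else float(np.sign(d) * np.inf),
            1.0 if d == 0 else 0.0,
            float(x.size + y.size - 2), (x.size, y.size),
            "t_two_sample_pooled" if equal_var else "t_two_sample_welch",
            degenerate=True,
        )
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    method = "t_two_sample_pooled" if equal_var else "t_two_sample_welch"
    return TestResult(float(res.statistic), float(res.pvalue),
                      float(res.df), (x.size, y.size), method)


def t_test_paired(x, y) -> TestResult:
    """Two-sided paired Student t on the differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired t-test needs equal-length inputs")
    res = t_test_one_sample(x - y, 0.0)
    res.method = "t_paired"
    res.n = (x.size,)
    return res


def regression_f_test(x, y) -> dict:
    """OLS of y on x with R^2 and the overall F-test p-value.

    For simple regression the overall F equals the squared slope t, so
    the F p-value coincides with the slope's two-sided t p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("regression needs >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("regression needs non-constant x")
    fit = sps.linregress(x, y)
    r2 = float(fit.rvalue**2)
    df = x.size - 2
    f_stat = float(fit.slope / fit.stderr) ** 2 if fit.stderr > 0 else np.inf
    test = TestResult(
        f_stat, float(fit.pvalue), float(df), (x.size,), "ols_f",
        extra={"slope": float(fit.slope), "intercept": float(fit.intercept)},
    )
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": r2,
        "test": test,
    }
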
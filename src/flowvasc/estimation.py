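"""Bootstrap-coupled estimation statistics and thin classical-test
plumbing.

Group comparisons are estimation-first: the primary output is the
observed mean difference together with its seeded bootstrap resampling
distribution and a percentile 95% confidence interval; Welch/t/
Mann-Whitney p-values are reported alongside, never instead.  The unit
of analysis (image, replicate or animal) is whatever the caller passes
in — this module never pools across declared units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class BootstrapEstimate:
    """Mean difference of two groups with a bootstrap CI.

    ``difference`` is mean(a) - mean(b).  ``ci_low <= difference <=
    ci_high`` for the percentile method on non-degenerate input.
    """

    difference: float
    ci_low: float
    ci_high: float
    boot_mean: float
    boot_sd: float
    n_a: int
    n_b: int
    n_boot: int
    seed: int
    ci_level: float = 95.0
    method: str = "percentile"
    bootstrap: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "difference": self.difference, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "boot_mean": self.boot_mean,
            "boot_sd": self.boot_sd, "n_a": self.n_a, "n_b": self.n_b,
            "n_boot": self.n_boot, "seed": self.seed,
            "ci_level": self.ci_level, "method": self.method}])


def bootstrap_mean_difference(a, b, n_boot: int = 5000, seed: int = 0,
                              ci_level: float = 95.0,
                              keep_distribution: bool = True
                              ) -> BootstrapEstimate:
    """Bootstrap distribution of mean(a) - mean(b).

    Each group is resampled with replacement ``n_boot`` times; the CI is
    the percentile interval of the resampled differences.  Fully seeded
    and reproducible.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if n_boot < 1000:
        raise ValueError("need at least 1000 bootstrap replicates")
    rng = np.random.default_rng(seed)
    boots_a = a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
    boots_b = b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
    diffs = boots_a - boots_b
    alpha = (100.0 - ci_level) / 2.0
    lo, hi = np.percentile(diffs, [alpha, 100.0 - alpha])
    return BootstrapEstimate(
        difference=float(a.mean() - b.mean()),
        ci_low=float(lo), ci_high=float(hi),
        boot_mean=float(diffs.mean()), boot_sd=float(diffs.std()),
        n_a=a.size, n_b=b.size, n_boot=n_boot, seed=seed, ci_level=ci_level,
        bootstrap=diffs if keep_distribution else None,
    )


def two_group_tests(a, b, test: str = "welch") -> tuple[float, float]:
    """Two-sided classical test: 'welch', 'ttest' (pooled variance) or
    'mannwhitney'.  Returns (statistic, p-value)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if test in ("welch", "ttest"):
        if np.std(a) == 0 and np.std(b) == 0:
            raise ValueError("degenerate input: both groups constant")
        res = stats.ttest_ind(a, b, equal_var=(test == "ttest"))
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
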
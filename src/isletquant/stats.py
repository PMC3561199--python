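"""Summary statistics and paired region comparisons.

Values are reported as mean ± SEM (SEM = sample sd / sqrt(n), n-1
denominator). PP-rich vs PP-poor area fractions are compared within
specimen by a two-sided paired Student's t-test, significant at alpha = 0.05
by default. Specimens lacking one of the two regions cannot be paired and
are excluded with an explicit log entry. No multiple-testing correction is
applied across the handful of endocrine types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .vslice import CELL_TYPES

#: Reference group mean ± SEM of area fractions (percent of tissue area)
#: reported for human pancreas specimens whose sections contained both a
#: PP-cell-rich and a PP-cell-poor region (n = 3 specimens). Used as the
#: default effect sizes when simulating paired cohorts.
HUMAN_RICH_POOR_REFERENCE: dict[str, tuple[float, float, float, float]] = {
    # type: (mean_rich, sem_rich, mean_poor, sem_poor)
    "pp": (1.2, 0.08, 0.01, 0.004),
    "beta": (0.3, 0.07, 0.7, 0.06),
    "alpha": (0.08, 0.03, 0.5, 0.01),
}

#: PP area fraction baseline (percent) in body and tail, mean ± SEM.
BODY_TAIL_PP_BASELINE = {"body": (0.02, 0.01), "tail": (0.02, 0.008)}


def mean_sem(values) -> tuple[float, float]:
    """Arithmetic mean and standard error of the mean.

    Raises
    ------
    ValueError
        For an empty input or a single value (SEM undefined at n = 1).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mean_sem requires at least one value")
    if x.size == 1:
        raise ValueError("SEM is undefined for a single value (n = 1)")
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size))


@dataclass
class PairedComparison:
    """Result of one paired rich-vs-poor comparison."""

    variable: str
    group_rich: list[float]
    group_poor: list[float]
    mean_rich: float
    sem_rich: float
    mean_poor: float
    sem_poor: float
    n_pairs: int
    t_statistic: float | None
    p_value: float | None
    significant: bool | None
    alpha: float = 0.05
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "mean_rich": self.mean_rich,
            "sem_rich": self.sem_rich,
            "mean_poor": self.mean_poor,
            "sem_poor": self.sem_poor,
            "n_pairs": self.n_pairs,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "significant": self.significant,
            "alpha": self.alpha,
            "warnings": list(self.warnings),
        }


def paired_t_test(
    pairs, variable: str = "value", alpha: float = 0.05
) -> PairedComparison:
    """Two-sided paired Student's t-test on (rich, poor) value pairs.

    t = mean(d) / (sd(d)/sqrt(n)) on differences d = rich - poor, with
    n - 1 degrees of freedom. Zero-variance differences short-circuit:
    p = 1 when all differences are zero (no effect), p = 0 when the constant
    difference is nonzero (infinitely strong evidence), both with a warning.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (rich, poor) tuples")
    n = arr.shape[0]
    if n < 2:
        raise ValueError("paired_t_test requires at least 2 pairs")
    rich, poor = arr[:, 0], arr[:, 1]
    d = rich - poor
    mean_rich, sem_rich = mean_sem(rich)
    mean_poor, sem_poor = mean_sem(poor)
    sd_d = float(d.std(ddof=1))
    warnings: list[str] = []
    if sd_d == 0.0:
        warnings.append("zero-variance differences; p set by mean difference")
        if d.mean() == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = float(np.sign(d.mean()) * np.inf)
            p = 0.0
    else:
        t_stat = float(d.mean() / (sd_d / np.sqrt(n)))
        p = float(2.0 * sps.t.sf(abs(t_stat), df=n - 1))
    return PairedComparison(
        variable=variable,
        group_rich=rich.tolist(),
        group_poor=poor.tolist(),
        mean_rich=mean_rich,
        sem_rich=sem_rich,
        mean_poor=mean_poor,
        sem_poor=sem_poor,
        n_pairs=n,
        t_statistic=t_stat,
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
        warnings=warnings,
    )


@dataclass
class SpecimenRegions:
    """Per-specimen measured values, one dict per region (or None if the
    specimen lacks that region — e.g. a head section entirely inside the
    PP-rich zone)."""

    specimen_id: str
    rich: dict[str, float] | None
    poor: dict[str, float] | None


def compare_regions(
    specimens: list[SpecimenRegions],
    variables: tuple[str, ...] = CELL_TYPES,
    alpha: float = 0.05,
) -> tuple[list[PairedComparison], list[str]]:
    """Paired rich-vs-poor comparison per variable across specimens.

    Specimens missing either region are excluded from pairing; the returned
    exclusion log names them. With fewer than 2 complete pairs the
    comparison is reported descriptively (no t or p).
    """
    complete = [s for s in specimens if s.rich is not None and s.poor is not None]
    exclusions = [
        f"specimen {s.specimen_id!r} excluded: "
        + ("missing PP-poor region" if s.poor is None else "missing PP-rich region")
        for s in specimens
        if s.rich is None or s.poor is None
    ]
    comparisons: list[PairedComparison] = []
    for var in variables:
        pairs = [
            (s.rich[var], s.poor[var])
            for s in complete
            if var in s.rich and var in s.poor
        ]
        if len(pairs) >= 2:
            comparisons.append(paired_t_test(pairs, variable=var, alpha=alpha))
        else:
            rich_vals = [p[0] for p in pairs]
            poor_vals = [p[1] for p in pairs]
            comparisons.append(
                PairedComparison(
                    variable=var,
                    group_rich=rich_vals,
                    group_poor=poor_vals,
                    mean_rich=float(np.mean(rich_vals)) if rich_vals else float("nan"),
                    sem_rich=float("nan"),
                    mean_poor=float(np.mean(poor_vals)) if poor_vals else float("nan"),
                    sem_poor=float("nan"),
                    n_pairs=len(pairs),
                    t_statistic=None,
                    p_value=None,
                    significant=None,
                    alpha=alpha,
                    warnings=["fewer than 2 complete pairs; descriptive only"],
                )
            )
    return comparisons, exclusions


def sample_paired_cohort(
    rng: np.random.Generator,
    reference: dict[str, tuple[float, float, float, float]] | None = None,
    n_specimens: int = 3,
) -> dict[str, np.ndarray]:
    """Draw synthetic per-specimen (rich, poor) area fractions.

    Specimen values are drawn independently from normal distributions whose
    means are the reference group means and whose sd is SEM * sqrt(n), i.e.
    the specimen-level spread implied by the reported group SEM at the
    reference cohort size.

    Returns ``{variable: array of shape (n_specimens, 2)}`` with columns
    (rich, poor).
    """
    reference = reference or HUMAN_RICH_POOR_REFERENCE
    out: dict[str, np.ndarray] = {}
    for var, (mr, sr, mp, sp) in reference.items():
        scale = np.sqrt(n_specimens)
        rich = rng.normal(mr, sr * scale, n_specimens)
        poor = rng.normal(mp, sp * scale, n_specimens)
        out[var] = np.column_stack([rich, poor])
    return out


def rejection_rate(
    seed: int,
    variable: str,
    n_replicates: int = 200,
    n_specimens: int = 3,
    alpha: float = 0.05,
    reference: dict[str, tuple[float, float, float, float]] | None = None,
) -> tuple[float, np.ndarray]:
    """Fraction of simulated paired cohorts rejecting the null, plus the
    per-replicate p-values."""
    reference = reference or HUMAN_RICH_POOR_REFERENCE
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_replicates)
    for i in range(n_replicates):
        cohort = sample_paired_cohort(rng, reference, n_specimens)
        pvals[i] = paired_t_test(cohort[variable], variable=variable).p_value
    return float((pvals < alpha).mean()), pvals
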
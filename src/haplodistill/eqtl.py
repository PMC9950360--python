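"""Additive cis-eQTL test: expression regressed on clade-2 dosage.

Each diploid sample carries 0, 1 or 2 clade-2 haplotypes; ordinary least
squares of expression on that dosage gives the effect per allele (beta),
its standard error, the variance explained (r^2, identical to the squared
Pearson correlation for simple regression) and a two-sided p-value from
the t distribution with n - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .datatypes import DataError, ExpressionTable, HaplotypeMatrix
from .distill import CladeAssignment


@dataclass
class EqtlResult:
    n: int
    beta: float
    se: float
    intercept: float
    r_squared: float
    p: float
    dropped_samples: list[str] = field(default_factory=list)


def dosage_code(
    matrix: HaplotypeMatrix, assignment: CladeAssignment
) -> tuple[dict[str, int], list[str]]:
    """Per-sample clade-2 dosage in {0, 1, 2}.

    Samples with any unassigned haplotype (missing tag allele, ambiguous
    clade) are excluded and returned separately.
    """
    hap_ids = matrix.haplotype_ids
    per_sample: dict[str, list[int]] = {}
    for h, s in zip(hap_ids, matrix.sample_ids):
        per_sample.setdefault(s, []).append(assignment.assignment.get(h, -1))
    dosages: dict[str, int] = {}
    dropped: list[str] = []
    for s, clades in per_sample.items():
        if len(clades) != 2 or -1 in clades:
            dropped.append(s)
            continue
        dosages[s] = sum(1 for c in clades if c == 2)
    return dosages, dropped


def fit_additive(dosages: dict[str, int], expression: ExpressionTable) -> EqtlResult:
    """OLS of expression on dosage, joined on sample id (inner join)."""
    expr = expression.as_dict()
    common = [s for s in dosages if s in expr]
    unmatched = sorted((set(dosages) | set(expr)) - set(common))
    if len(common) < 3:
        raise DataError(f"only {len(common)} samples after joining; need >= 3")
    x = [float(dosages[s]) for s in common]
    y = [expr[s] for s in common]
    if len(set(x)) < 2:
        raise DataError("monomorphic locus: zero dosage variance")
    fit = stats.linregress(x, y)
    return EqtlResult(
        n=len(common),
        beta=float(fit.slope),
        se=float(fit.stderr),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
        dropped_samples=unmatched,
    )


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH-adjusted q-values for multi-gene batch use (single-locus runs do
    not need correction)."""
    return list(stats.false_discovery_control(pvalues, method="bh"))
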
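"""Archaic-genome concordance, outgroup-calibrated dating, and the expected
length of an unbroken haplotype block.

Concordance asks: at the sites of the core haplotype, does an archaic
individual carry the clade-2 consensus base?  Heterozygous archaic calls
(IUPAC codes) are tallied separately — they never enter the homozygous
match percentage — with a flag for whether one of their two alleles
matches.

Dating converts relative sequence divergence into years by anchoring the
mean distance to an outgroup at a known calibration age (6 My for the
human-chimpanzee split): t = T_cal x d_focal / d_calibration.

The expected unbroken block length for a haplotype of age t is
L = 1 / (c g), with c the recombination rate in crossovers per bp per
generation and g the age in generations: an old haplotype should long ago
have been whittled down to short segments unless recombination is locally
suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ArchaicGenotypeTable, DataError


@dataclass
class ConcordanceReport:
    """Site tallies of one archaic individual against a clade consensus."""

    individual_id: str
    reference_clade: int
    n_sites_available: int
    n_het: int
    n_het_sharing: int  # het sites where one allele matches the clade consensus
    n_hom: int
    n_hom_match: int

    def __post_init__(self) -> None:
        if self.n_sites_available != self.n_het + self.n_hom:
            raise DataError("site tallies do not add up")
        if self.n_hom_match > self.n_hom or self.n_het_sharing > self.n_het:
            raise DataError("match counts exceed site counts")

    @property
    def pct_hom_match(self) -> float:
        """Homozygous-site concordance, percent to one decimal."""
        if self.n_hom == 0:
            return float("nan")
        return round(100.0 * self.n_hom_match / self.n_hom, 1)

    @property
    def pct_any_match(self) -> float:
        """Secondary figure: sites where any carried allele matches."""
        if self.n_sites_available == 0:
            return float("nan")
        return round(
            100.0 * (self.n_hom_match + self.n_het_sharing) / self.n_sites_available, 1
        )


def concordance(
    core: pd.DataFrame,
    archaic: ArchaicGenotypeTable,
    reference_clade: int = 2,
) -> ConcordanceReport:
    """Score an archaic individual against a clade's core haplotype.

    ``core`` is the table from :func:`haplodistill.distill.core_haplotypes`
    (columns pos, ref_allele, alt_allele, cladeN_allele, resolved).  Only
    sites present in both tables are compared; unresolved core sites are
    excluded.  Homozygous archaic calls are compared to the consensus base;
    heterozygous calls are tallied separately with a one-allele-matches
    flag.
    """
    if reference_clade not in (1, 2):
        raise DataError("reference_clade must be 1 or 2")
    col = f"clade{reference_clade}_allele"
    n_het = n_het_sharing = n_hom = n_hom_match = 0
    for _, row in core.iterrows():
        pos = int(row["pos"])
        if pos not in archaic.calls:
            continue
        if not row["resolved"] or row[col] not in (0, 1):
            continue
        clade_base = row["alt_allele"] if row[col] == 1 else row["ref_allele"]
        bases = archaic.bases(pos)
        if archaic.is_het(pos):
            n_het += 1
            if clade_base in bases:
                n_het_sharing += 1
        else:
            n_hom += 1
            if clade_base in bases:
                n_hom_match += 1
    if n_het + n_hom == 0:
        raise DataError(
            f"no overlapping resolved sites between core table and "
            f"{archaic.individual_id}"
        )
    return ConcordanceReport(
        individual_id=archaic.individual_id,
        reference_clade=reference_clade,
        n_sites_available=n_het + n_hom,
        n_het=n_het,
        n_het_sharing=n_het_sharing,
        n_hom=n_hom,
        n_hom_match=n_hom_match,
    )


# ---------------------------------------------------------------------------
# Dating
# ---------------------------------------------------------------------------


@dataclass
class DatingResult:
    t_years: float
    d_focal: float
    d_calibration: float
    T_calibration_years: float
    n_focal_pairs: int
    n_calibration_pairs: int


def _mean_cross_distance(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Mean Hamming distance over all cross pairs of rows(a) x rows(b),
    with pairwise deletion of NaN sites.  Entries of 0.5 (archaic het)
    count half a difference."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    total = 0.0
    n_pairs = 0
    for x in a:
        for y in b:
            ok = ~np.isnan(x) & ~np.isnan(y)
            if not ok.any():
                continue
            total += float(np.abs(x[ok] - y[ok]).sum())
            n_pairs += 1
    if n_pairs == 0:
        raise DataError("no comparable sequence pairs")
    return total / n_pairs, n_pairs


def date_divergence(
    group_a: np.ndarray,
    group_b: np.ndarray,
    outgroup: np.ndarray,
    T_calibration_years: float = 6.0e6,
) -> DatingResult:
    """Outgroup-calibrated divergence time between two haplotype groups.

    ``group_a``/``group_b`` are (haplotypes x sites) 0/1 arrays (NaN for
    missing, 0.5 allowed for archaic het pseudo-haplotypes); ``outgroup``
    is a single aligned sequence.  The focal divergence is the mean
    Hamming distance over cross pairs; the calibration is the mean
    distance of all ingroup haplotypes to the outgroup.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    d_focal, n_focal = _mean_cross_distance(a, b)
    ingroup = np.vstack([a, b])
    d_cal, n_cal = _mean_cross_distance(ingroup, np.atleast_2d(outgroup))
    if d_cal == 0:
        raise DataError("zero divergence to outgroup; cannot calibrate")
    return DatingResult(
        t_years=T_calibration_years * d_focal / d_cal,
        d_focal=d_focal,
        d_calibration=d_cal,
        T_calibration_years=T_calibration_years,
        n_focal_pairs=n_focal,
        n_calibration_pairs=n_cal,
    )


# ---------------------------------------------------------------------------
# Expected block length
# ---------------------------------------------------------------------------


def expected_block_length(
    t_years: float, gen_time_years: float, rec_rate_cM_per_Mb: float
) -> float:
    """Expected unbroken segment length (bp) for a haplotype of age t.

    L = 1 / (c g): c = rec_rate x 1e-8 crossovers per bp per generation
    (1 cM/Mb = 1e-8 per bp), g = t_years / gen_time_years generations.
    """
    if t_years <= 0 or gen_time_years <= 0 or rec_rate_cM_per_Mb <= 0:
        raise DataError("all block-length inputs must be positive")
    c = rec_rate_cM_per_Mb * 1e-8
    g = t_years / gen_time_years
    return 1.0 / (c * g)
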
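"""Core data containers shared by every pipeline stage.

The central object is :class:`HaplotypeMatrix`, a phased 0/1 allele matrix
(variants x haplotypes) with per-haplotype sample labels and a
sample -> population mapping.  Missing alleles are coded ``-1``.
Coordinates are 1-based inclusive throughout, following VCF convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

MISSING = -1

#: IUPAC two-base ambiguity codes used for heterozygous archaic calls.
IUPAC_HET = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}

VALID_BASES = frozenset("ACGT")


class DataError(ValueError):
    """Structural or semantic problem in an input table."""


@dataclass(frozen=True)
class VariantRecord:
    """A single biallelic variant (SNP or indel)."""

    chrom: str
    pos: int  # 1-based bp
    vid: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"variant {self.vid}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise DataError(f"variant {self.vid}: ref and alt alleles are identical")

    @property
    def vclass(self) -> str:
        """``snp`` when both alleles are single bases, else ``indel``."""
        return "snp" if len(self.ref_allele) == 1 and len(self.alt_allele) == 1 else "indel"


class HaplotypeMatrix:
    """Phased allele matrix over variants (rows) and haplotypes (columns).

    Parameters
    ----------
    variants :
        Variant records sorted strictly increasing by position.
    alleles :
        Integer matrix of 0 (reference), 1 (alternate) and -1 (missing),
        shape ``(len(variants), n_haplotypes)``.
    sample_ids :
        One sample label per haplotype column; diploid samples contribute
        two adjacent columns.
    population :
        Mapping sample id -> population code (may be empty when no panel
        was supplied).
    superpopulation :
        Optional mapping population code -> superpopulation code.
    """

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        alleles: np.ndarray,
        sample_ids: Sequence[str],
        population: Mapping[str, str] | None = None,
        superpopulation: Mapping[str, str] | None = None,
    ) -> None:
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.ndim != 2:
            raise DataError("allele matrix must be 2-dimensional")
        if alleles.shape[0] != len(variants):
            raise DataError(
                f"{len(variants)} variants but {alleles.shape[0]} allele rows"
            )
        if alleles.shape[1] != len(sample_ids):
            raise DataError(
                f"{len(sample_ids)} haplotype labels but {alleles.shape[1]} columns"
            )
        bad = set(np.unique(alleles)) - {0, 1, MISSING}
        if bad:
            raise DataError(f"allele codes outside {{0,1,-1}}: {sorted(bad)}")
        pos = [v.pos for v in variants]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise DataError("variants must be sorted strictly increasing by pos")
        self.variants = list(variants)
        self.alleles = alleles
        self.sample_ids = list(sample_ids)
        self.population = dict(population or {})
        self.superpopulation = dict(superpopulation or {})
        for s, p in self.population.items():
            if not p:
                raise DataError(f"sample {s}: empty population code")

    # -- basic geometry -------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def haplotype_ids(self) -> list[str]:
        """Stable per-column labels, ``sample|0`` / ``sample|1`` for diploids."""
        counts: dict[str, int] = {}
        out = []
        for s in self.sample_ids:
            k = counts.get(s, 0)
            counts[s] = k + 1
            out.append(f"{s}|{k}")
        return out

    def vid_index(self, vid: str) -> int:
        for i, v in enumerate(self.variants):
            if v.vid == vid:
                return i
        raise KeyError(f"variant id {vid!r} not in matrix")

    def subset_positions(self, start: int, end: int) -> "HaplotypeMatrix":
        """Rows with start <= pos <= end (1-based inclusive)."""
        keep = [i for i, v in enumerate(self.variants) if start <= v.pos <= end]
        return self.subset_rows(keep)

    def subset_rows(self, idx: Sequence[int]) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            [self.variants[i] for i in idx],
            self.alleles[list(idx), :],
            self.sample_ids,
            self.population,
            self.superpopulation,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.alleles, other.alleles)
        )

    def __repr__(self) -> str:
        return (
            f"HaplotypeMatrix({self.n_variants} variants x "
            f"{self.n_haplotypes} haplotypes)"
        )


@dataclass
class ArchaicGenotypeTable:
    """Diploid genotype calls of one archaic individual, one call per position.

    A call is a single base (homozygote), an IUPAC two-base ambiguity code
    (heterozygote), or absent/``N`` (missing).
    """

    individual_id: str
    calls: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, call in self.calls.items():
            if call not in VALID_BASES and call not in IUPAC_HET:
                raise DataError(
                    f"{self.individual_id} pos {pos}: invalid genotype code {call!r}"
                )

    def is_het(self, pos: int) -> bool:
        return self.calls.get(pos, "N") in IUPAC_HET

    def bases(self, pos: int) -> frozenset[str]:
        """The set of bases carried at ``pos`` (1 for hom, 2 for het)."""
        call = self.calls[pos]
        return IUPAC_HET.get(call, frozenset(call))

    def __len__(self) -> int:
        return len(self.calls)


@dataclass
class AncientSampleTable:
    """Dated ancient samples with diploid derived-allele counts at tag variants.

    ``genotypes`` maps tag variant id -> {0, 1, 2} derived-allele count;
    missing tags are simply absent from the mapping.
    """

    samples: list[str]
    ages_years_bp: list[float]
    genotypes: list[dict[str, int]]

    def __post_init__(self) -> None:
        if not (len(self.samples) == len(self.ages_years_bp) == len(self.genotypes)):
            raise DataError("ancient table columns have unequal lengths")
        for s, a in zip(self.samples, self.ages_years_bp):
            if a < 0:
                raise DataError(f"ancient sample {s}: negative age {a}")
        for s, g in zip(self.samples, self.genotypes):
            for vid, cnt in g.items():
                if cnt not in (0, 1, 2):
                    raise DataError(f"ancient sample {s}, tag {vid}: count {cnt}")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class ExpressionTable:
    """Per-sample expression values (FPKM units, non-negative)."""

    samples: list[str]
    values: list[float]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.values):
            raise DataError("expression table columns have unequal lengths")
        for s, v in zip(self.samples, self.values):
            if v < 0:
                raise DataError(f"sample {s}: negative expression {v}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.samples, self.values))

    def __len__(self) -> int:
        return len(self.samples)
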
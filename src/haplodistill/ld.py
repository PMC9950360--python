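"""Pairwise linkage disequilibrium on phased haplotypes and tag-anchored blocks.

Because the data are phased, haplotype frequencies are obtained by direct
counting and r-squared is the squared correlation of the two 0/1 allele
indicator vectors:

    r^2 = (p_AB - p_A p_B)^2 / (p_A (1 - p_A) p_B (1 - p_B))

Missing haplotypes are removed pairwise per pair of sites.  A block is
anchored on a tag variant: every variant with r^2 >= threshold against the
tag belongs to the block (a strict mode additionally verifies all
within-block pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import MISSING, DataError, HaplotypeMatrix


class MonomorphicError(DataError):
    """LD is undefined against a monomorphic column."""


def r2_pair(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Haplotype-based r-squared between two phased 0/1 allele columns.

    Missing entries (-1) in either column are excluded pairwise.  Raises
    :class:`MonomorphicError` when either column is monomorphic among the
    jointly non-missing haplotypes.
    """
    a = np.asarray(col_a)
    b = np.asarray(col_b)
    keep = (a != MISSING) & (b != MISSING)
    a, b = a[keep].astype(float), b[keep].astype(float)
    n = a.size
    if n < 2:
        raise MonomorphicError("fewer than 2 jointly non-missing haplotypes")
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicError("monomorphic column after pairwise deletion")
    p_ab = float(np.mean(a * b))
    d = p_ab - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


@dataclass
class LDBlock:
    """Variants in strong LD with a tag, with their physical span."""

    member_vids: list[str]
    span_start: int
    span_end: int
    tag_vid: str
    threshold: float
    r2_with_tag: dict[str, float] = field(default_factory=dict)
    #: vids where r2 against the tag was undefined (monomorphic); not members
    undefined_vids: list[str] = field(default_factory=list)
    #: in strict mode, within-block pairs below threshold
    violating_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def span_bp(self) -> int:
        return self.span_end - self.span_start


def ld_block_from_tag(
    matrix: HaplotypeMatrix,
    tag_vid: str,
    threshold: float = 0.8,
    strict: bool = False,
) -> LDBlock:
    """Delineate the LD block anchored on ``tag_vid``.

    Members are the tag plus every variant whose r-squared with the tag is
    at or above ``threshold``.  Variants monomorphic against the tag are
    reported as undefined rather than treated as r2 = 0.  With
    ``strict=True`` all within-block pairs are checked and sub-threshold
    pairs reported (membership is still tag-anchored).
    """
    ti = matrix.vid_index(tag_vid)
    tag_col = matrix.alleles[ti]
    members: list[int] = []
    r2s: dict[str, float] = {}
    undefined: list[str] = []
    for i, v in enumerate(matrix.variants):
        if i == ti:
            members.append(i)
            r2s[v.vid] = 1.0
            continue
        try:
            r2 = r2_pair(matrix.alleles[i], tag_col)
        except MonomorphicError:
            if i == ti:
                raise
            undefined.append(v.vid)
            continue
        r2s[v.vid] = r2
        if r2 >= threshold:
            members.append(i)
    # tag itself must be polymorphic
    tag_nonmiss = tag_col[tag_col != MISSING]
    if tag_nonmiss.size == 0 or len(set(tag_nonmiss.tolist())) < 2:
        raise MonomorphicError(f"tag variant {tag_vid} is monomorphic")
    positions = [matrix.variants[i].pos for i in members]
    block = LDBlock(
        member_vids=[matrix.variants[i].vid for i in members],
        span_start=min(positions),
        span_end=max(positions),
        tag_vid=tag_vid,
        threshold=threshold,
        r2_with_tag=r2s,
        undefined_vids=undefined,
    )
    if strict:
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                i, j = members[ai], members[bi]
                try:
                    r2 = r2_pair(matrix.alleles[i], matrix.alleles[j])
                except MonomorphicError:
                    continue
                if r2 < threshold:
                    block.violating_pairs.append(
                        (matrix.variants[i].vid, matrix.variants[j].vid, r2)
                    )
    return block
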
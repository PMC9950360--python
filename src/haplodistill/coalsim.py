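"""Neutral coalescent simulation and the two-clade balanced-haplotype generator.

Two generators share one engine:

* :func:`simulate_neutral` — a standard Hudson coalescent without
  recombination.  Time is measured in units of 2N generations; k lineages
  coalesce at rate C(k,2).  Mutations follow the infinite-sites model,
  either Poisson(theta/2 x total branch length) (theta-mode) or exactly
  ``S_fixed`` mutations placed multinomially on branches proportional to
  length (fixed-S mode, the classical conditioning used for null
  distributions of Tajima's D).

* :func:`simulate_two_clade` — the balanced-polymorphism scenario: two
  clades of sampled haplotypes coalesce internally (in generations, with
  diploid size N_e), their root lineages join deterministically at
  ``T_split`` generations ago, an archaic lineage branches off the clade-2
  stem at ``T_archaic``, and an outgroup diverges at ``T_outgroup``.
  Within-clade genealogies whose TMRCA would overshoot the stem are
  rejected and redrawn (counts surfaced).  Clade-defining stem mutations
  can be concentrated inside a designated target segment, emulating the
  dense divergent core that a selection scan should localise.

All randomness flows from a single counter-based Philox stream seeded with
one integer, so identical parameters and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .datatypes import (
    AncientSampleTable,
    ArchaicGenotypeTable,
    DataError,
    ExpressionTable,
    HaplotypeMatrix,
    VariantRecord,
)

_BASES = np.array(list("ACGT"))
_HET_CODE = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


@dataclass
class SimParams:
    """Parameters for both simulator modes.

    Neutral mode uses ``n`` plus ``theta`` or ``S_fixed``.  Two-clade mode
    uses the clade sample sizes and the split/archaic/outgroup times (in
    generations); defaults correspond to a 1.54 My clade split, a 729 ky
    archaic branch-off and a 6 My outgroup divergence at 25 years per
    generation, over a 70 kb locus with a dense 3 kb central target.
    """

    # shared
    seed: int = 0
    L: int = 10_000
    chrom: str = "chr4"
    region_start: int = 1  # physical offset of the simulated locus

    # neutral mode
    n: int = 20
    theta: float | None = 10.0
    S_fixed: int | None = None

    # two-clade mode
    n1: int = 135
    n2: int = 65
    N_e: float = 5_000.0  # within-clade effective size (an allele class held
    # at intermediate frequency coalesces like a population of f x N diploids)
    T_split: float = 61_600.0  # generations (1.54 My / 25)
    T_archaic: float = 29_160.0  # generations (729 ky / 25)
    T_outgroup: float = 240_000.0  # generations (6 My / 25)
    mu_per_site: float = 1.25e-8  # per generation
    gen_time_years: float = 25.0
    target_start: int | None = None  # defaults to the central 3 kb
    target_end: int | None = None
    target_frac: float = 0.4  # fraction of stem mutations drawn inside the target
    archaic_het_rate: float = 0.016  # per-site heterozygosity of the archaic diploid

    def __post_init__(self) -> None:
        if not (self.T_archaic < self.T_split < self.T_outgroup):
            raise DataError("need T_archaic < T_split < T_outgroup")
        if self.N_e <= 0 or self.mu_per_site <= 0 or self.L <= 0:
            raise DataError("rates and sizes must be positive")


@dataclass
class SimulationTruth:
    """Ground truth of a two-clade replicate, for recovery tests."""

    clade_labels: dict[str, int]  # haplotype id -> 1 or 2
    stem_positions: list[int]  # clade-defining (fixed inter-clade) sites
    #: stem sites younger than the archaic attachment (clade-2 stem between
    #: its crown and T_archaic); the archaic does not carry these
    post_archaic_stem_positions: list[int]
    tmrca1_gens: float
    tmrca2_gens: float
    rejections: dict[str, int]
    target_segment: tuple[int, int]
    seed: int
    #: True when the archaic lineage attached to the clade-2 stem (TMRCA2
    #: younger than T_archaic) rather than inside the clade-2 crown
    archaic_on_stem: bool = False


@dataclass
class TwoCladeResult:
    matrix: HaplotypeMatrix
    archaic: ArchaicGenotypeTable
    #: archaic alleles aligned to matrix.variants: 0/1, 0.5 at het sites
    archaic_alleles: np.ndarray
    #: outgroup alleles aligned to matrix.variants (0/1)
    outgroup: np.ndarray
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# Genealogy engine
# ---------------------------------------------------------------------------


def _coalesce(
    rng: np.random.Generator, n: int, rate_scale: float = 1.0
) -> tuple[list[tuple[frozenset[int], float, float]], float]:
    """Run a plain coalescent on ``n`` lineages.

    Returns (branches, tmrca) where each branch is (descendant leaf set,
    birth time, death time) looking backwards from the present (leaves are
    born at 0, a branch dies when it coalesces).  Waiting times are
    exponential with mean ``rate_scale / C(k,2)``; with ``rate_scale = 1``
    time is in units of 2N generations, with ``rate_scale = 2 N_e`` it is
    in generations.
    """
    lineages: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    born = [0.0] * n
    branches: list[tuple[frozenset[int], float, float]] = []
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(rate_scale / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        branches.append((lineages[i], born[i], t))
        branches.append((lineages[j], born[j], t))
        merged = lineages[i] | lineages[j]
        lineages = [l for m, l in enumerate(lineages) if m not in (i, j)] + [merged]
        born = [b for m, b in enumerate(born) if m not in (i, j)] + [t]
    return branches, t


def _unique_positions(
    rng: np.random.Generator,
    counts: Sequence[int],
    L: int,
    used: set[int],
    target: tuple[int, int] | None = None,
    target_frac: float = 0.0,
) -> list[list[int]]:
    """Draw integer positions in [1, L], unique across the whole locus
    (infinite sites).  With a target window, each position falls uniformly
    inside it with probability ``target_frac``, else uniformly genome-wide.
    """
    total = sum(counts)
    if total + len(used) > L:
        raise DataError(f"cannot place {total} mutations on {L} sites (infinite sites)")
    out: list[list[int]] = []
    for c in counts:
        got: list[int] = []
        while len(got) < c:
            if target is not None and rng.random() < target_frac:
                p = int(rng.integers(target[0], target[1] + 1))
            else:
                p = int(rng.integers(1, L + 1))
            if p not in used:
                used.add(p)
                got.append(p)
        out.append(got)
    return out


def _make_variants(
    rng: np.random.Generator, positions: Sequence[int], chrom: str, offset: int
) -> list[VariantRecord]:
    recs = []
    for p in positions:
        ref, alt = rng.choice(4, size=2, replace=False)
        pos = offset + p - 1
        recs.append(
            VariantRecord(chrom, pos, f"var{pos}", str(_BASES[ref]), str(_BASES[alt]))
        )
    return recs


# ---------------------------------------------------------------------------
# Neutral mode
# ---------------------------------------------------------------------------


def simulate_neutral(params: SimParams) -> HaplotypeMatrix:
    """One neutral coalescent replicate as a HaplotypeMatrix.

    theta-mode places Poisson(theta/2 x total branch length) mutations;
    fixed-S mode places exactly ``S_fixed``.  Positions are uniform unique
    integers on [1, L].
    """
    if params.n < 2:
        raise DataError("need n >= 2")
    rng = np.random.Generator(np.random.Philox(params.seed))
    branches, _ = _coalesce(rng, params.n)
    lengths = np.array([e - s for _, s, e in branches])
    total = lengths.sum()
    if params.S_fixed is not None:
        n_mut = int(params.S_fixed)
    elif params.theta is not None:
        n_mut = int(rng.poisson(params.theta / 2.0 * total))
    else:
        raise DataError("neutral mode needs theta or S_fixed")
    which = rng.choice(len(branches), size=n_mut, p=lengths / total) if n_mut else []
    positions = _unique_positions(rng, [n_mut], params.L, set())[0]
    cols = np.zeros((n_mut, params.n), dtype=np.int8)
    for m, b in enumerate(which):
        cols[m, list(branches[b][0])] = 1
    order = np.argsort(positions)
    variants = _make_variants(
        rng, [positions[i] for i in order], params.chrom, params.region_start
    )
    sample_ids = [f"H{i:04d}" for i in range(params.n)]
    return HaplotypeMatrix(variants, cols[order], sample_ids)


# ---------------------------------------------------------------------------
# Two-clade mode
# ---------------------------------------------------------------------------


def simulate_two_clade(params: SimParams) -> TwoCladeResult:
    """The balanced two-clade scenario with archaic and outgroup lineages.

    The emitted matrix contains the modern haplotypes only (columns shuffled
    into diploid samples by a seeded permutation); the archaic diploid and
    the outgroup come back as aligned allele vectors plus an
    :class:`ArchaicGenotypeTable` of base calls (IUPAC codes at simulated
    heterozygous sites).  Sites where only the archaic or outgroup lineage
    mutated are retained (monomorphic rows in the modern matrix) so that
    every sequence lives on one shared site set.
    """
    p = params
    if p.n1 < 1 or p.n2 < 1:
        raise DataError("need n1, n2 >= 1")
    rng = np.random.Generator(np.random.Philox(p.seed))
    rej = {"clade1": 0, "clade2": 0}
    # within-clade genealogies, rejected until they fit under the split
    while True:
        b1, tmrca1 = _coalesce(rng, p.n1, rate_scale=2.0 * p.N_e)
        if tmrca1 <= p.T_split:
            break
        rej["clade1"] += 1
    # clade 2 is additionally conditioned on a crown younger than the archaic
    # attachment, so the archaic lineage joins the clade-2 stem and is
    # monophyletic with the whole clade
    while True:
        b2, tmrca2 = _coalesce(rng, p.n2, rate_scale=2.0 * p.N_e)
        if tmrca2 <= p.T_archaic:
            break
        rej["clade2"] += 1
    # >= 10 consecutive rejections before one acceptance indicates a
    # rejection rate well above 50%
    for key in ("clade1", "clade2"):
        if rej[key] >= 10:
            import warnings

            warnings.warn(
                f"{key}: {rej[key]} rejected genealogies; consider a larger "
                "T_split or smaller N_e",
                stacklevel=2,
            )

    n_mod = p.n1 + p.n2
    ARCH, OUT = n_mod, n_mod + 1  # pseudo-column indices
    clade1_cols = frozenset(range(p.n1))
    clade2_cols = frozenset(range(p.n1, n_mod))
    ingroup = clade1_cols | clade2_cols | {ARCH}

    # The archaic lineage attaches at T_archaic to whichever clade-2
    # ancestral lineage is active then: a crown lineage when the clade-2
    # TMRCA predates the attachment, the clade-2 stem otherwise.  Every
    # branch ancestral to the attachment point gains the archaic as a
    # descendant, so all clade-defining mutations older than T_archaic are
    # shared with the archaic by construction.
    b2 = [(frozenset(i + p.n1 for i in d), s, e) for d, s, e in b2]
    on_stem = tmrca2 <= p.T_archaic
    chosen: frozenset[int] | None = None
    if not on_stem:
        active = [k for k, (_, s, e) in enumerate(b2) if s <= p.T_archaic < e]
        chosen = b2[active[int(rng.integers(len(active)))]][0]

    # branch catalogue: (descendant set, length in generations, is_stem)
    branches: list[tuple[frozenset[int], float, bool]] = []
    for d, s, e in b1:
        branches.append((d, e - s, False))
    branches.append((clade1_cols, p.T_split - tmrca1, True))  # clade-1 stem
    for d, s, e in b2:
        if chosen is not None and d == chosen and s <= p.T_archaic < e:
            branches.append((d, p.T_archaic - s, False))
            branches.append((d | {ARCH}, e - p.T_archaic, False))
        elif chosen is not None and d > chosen:
            branches.append((d | {ARCH}, e - s, False))  # ancestor of attachment
        else:
            branches.append((d, e - s, False))
    if on_stem:
        # the clade-2 stem piece below the attachment is clade-defining but
        # not shared with the archaic
        branches.append((clade2_cols, p.T_archaic - tmrca2, True))
        branches.append((clade2_cols | {ARCH}, p.T_split - p.T_archaic, True))
    else:
        branches.append((clade2_cols | {ARCH}, p.T_split - tmrca2, True))
    branches.append((frozenset({ARCH}), p.T_archaic, False))  # archaic terminal
    branches.append((ingroup, p.T_outgroup - p.T_split, False))  # root path
    branches.append((frozenset({OUT}), p.T_outgroup, False))  # outgroup terminal

    target = (
        (p.target_start, p.target_end)
        if p.target_start is not None and p.target_end is not None
        else (p.L // 2 - 1500 + 1, p.L // 2 + 1500)
    )
    used: set[int] = set()
    mean_mut = [p.mu_per_site * p.L * ln for _, ln, _ in branches]
    counts = [int(rng.poisson(m)) for m in mean_mut]
    site_pos: list[int] = []
    site_carriers: list[frozenset[int]] = []
    stem_pos: list[int] = []
    post_archaic_stem: list[int] = []
    for (desc, _, is_stem), c in zip(branches, counts):
        pos_list = _unique_positions(
            rng, [c], p.L, used,
            target=target if is_stem else None,
            target_frac=p.target_frac if is_stem else 0.0,
        )[0]
        for q in pos_list:
            site_pos.append(q)
            site_carriers.append(desc)
            if is_stem:
                stem_pos.append(p.region_start + q - 1)
                if ARCH not in desc and desc == clade2_cols:
                    post_archaic_stem.append(p.region_start + q - 1)

    order = np.argsort(site_pos)
    n_sites = len(site_pos)
    full = np.zeros((n_sites, n_mod + 2), dtype=np.int8)
    for row, k in enumerate(order):
        full[row, list(site_carriers[k])] = 1
    variants = _make_variants(
        rng, [site_pos[k] for k in order], p.chrom, p.region_start
    )

    # shuffle modern columns into diploid samples
    perm = rng.permutation(n_mod)
    modern = full[:, :n_mod][:, perm]
    diploid = n_mod % 2 == 0
    if diploid:
        sample_ids = [f"S{i:04d}" for i in range(n_mod // 2) for _ in range(2)]
    else:
        sample_ids = [f"S{i:04d}" for i in range(n_mod)]
    matrix = HaplotypeMatrix(variants, modern, sample_ids)
    hap_ids = matrix.haplotype_ids
    clade_labels = {
        hap_ids[new]: (1 if orig < p.n1 else 2) for new, orig in enumerate(perm)
    }

    # archaic diploid: homozygous for its lineage allele, with optional
    # heterozygous sites emitted as IUPAC ambiguity codes
    arch = full[:, ARCH].astype(float)
    het_mask = rng.random(n_sites) < p.archaic_het_rate
    calls: dict[int, str] = {}
    for i, v in enumerate(variants):
        carried = v.alt_allele if full[i, ARCH] == 1 else v.ref_allele
        if het_mask[i] and v.vclass == "snp":
            other = v.ref_allele if carried == v.alt_allele else v.alt_allele
            calls[v.pos] = _HET_CODE[frozenset({carried, other})]
            arch[i] = 0.5
        else:
            calls[v.pos] = carried
    archaic_table = ArchaicGenotypeTable("sim_archaic", calls)

    truth = SimulationTruth(
        clade_labels=clade_labels,
        stem_positions=sorted(stem_pos),
        post_archaic_stem_positions=sorted(post_archaic_stem),
        tmrca1_gens=tmrca1,
        tmrca2_gens=tmrca2,
        rejections=rej,
        target_segment=(
            p.region_start + target[0] - 1,
            p.region_start + target[1] - 1,
        ),
        seed=p.seed,
        archaic_on_stem=on_stem,
    )
    return TwoCladeResult(
        matrix=matrix,
        archaic=archaic_table,
        archaic_alleles=arch,
        outgroup=full[:, OUT].copy(),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Replicate summaries (null distributions, calibration)
# ---------------------------------------------------------------------------


def neutral_replicates(
    n: int,
    theta: float | None = None,
    S_fixed: int | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Summary statistics of ``n_reps`` neutral replicates.

    Returns a structured array with fields S, pi_total and D (NaN when
    undefined).  Mutation carrier counts suffice for all three statistics,
    so no allele matrices are materialised; this is the fast path behind
    the scan's simulated null distribution of Tajima's D.
    """
    from .scan import tajimas_d_from_parts  # local import avoids a cycle

    rng = np.random.Generator(np.random.Philox(seed))
    out = np.zeros(n_reps, dtype=[("S", "i8"), ("pi_total", "f8"), ("D", "f8")])
    n_pairs = n * (n - 1) / 2.0
    for r in range(n_reps):
        branches, _ = _coalesce(rng, n)
        lengths = np.array([e - s for _, s, e in branches])
        total = lengths.sum()
        if S_fixed is not None:
            n_mut = int(S_fixed)
        elif theta is not None:
            n_mut = int(rng.poisson(theta / 2.0 * total))
        else:
            raise DataError("need theta or S_fixed")
        if n_mut:
            which = rng.choice(len(branches), size=n_mut, p=lengths / total)
            carriers = np.array([len(branches[b][0]) for b in which])
            S = n_mut  # infinite sites: every mutation is its own segregating site
            pi = float((carriers * (n - carriers)).sum() / n_pairs)
        else:
            S, pi = 0, 0.0
        d = tajimas_d_from_parts(S, pi, n)
        out[r] = (S, pi, np.nan if d is None else d)
    return out


# ---------------------------------------------------------------------------
# Downstream synthetic layers
# ---------------------------------------------------------------------------


def simulate_expression(
    dosages: Mapping[str, int],
    beta: float,
    sigma: float,
    seed: int,
    intercept: float = 5.0,
) -> ExpressionTable:
    """Expression = intercept + beta x clade-2 dosage + N(0, sigma^2), floored at 0."""
    rng = np.random.Generator(np.random.Philox(seed))
    samples = list(dosages)
    noise = rng.normal(0.0, sigma, size=len(samples))
    values = [
        max(0.0, intercept + beta * dosages[s] + e) for s, e in zip(samples, noise)
    ]
    return ExpressionTable(samples, values)


def beta_for_r2(r2: float, sigma: float, clade2_freq: float) -> float:
    """Effect size giving expected variance explained ``r2`` under
    Hardy-Weinberg dosages: r2 = beta^2 Var(g) / (beta^2 Var(g) + sigma^2)
    with Var(g) = 2 f (1 - f)."""
    var_g = 2.0 * clade2_freq * (1.0 - clade2_freq)
    return float(np.sqrt(r2 / (1.0 - r2) * sigma**2 / var_g))


def simulate_ancient_samples(
    freq_by_age: Callable[[float], float],
    tag_clade2_allele: Mapping[str, int],
    n_per_bin: int = 10,
    bin_width_years: float = 2000.0,
    max_age_years: float = 45000.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> AncientSampleTable:
    """Dated diploid samples with Binomial(2, f(age)) clade-2 tag genotypes.

    Genotypes are stored as derived(ALT)-allele counts, so tags whose
    clade-2 allele is the reference are flipped via ``tag_clade2_allele``.
    """
    rng = np.random.Generator(np.random.Philox(seed))
    edges = np.arange(0.0, max_age_years + bin_width_years, bin_width_years)
    samples, ages, genos = [], [], []
    idx = 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        for _ in range(n_per_bin):
            age = float(rng.uniform(lo, hi))
            f = freq_by_age(age)
            if not 0.0 <= f <= 1.0:
                raise DataError(f"frequency {f} at age {age} outside [0,1]")
            g: dict[str, int] = {}
            for vid, a2 in tag_clade2_allele.items():
                if rng.random() < missing_rate:
                    continue
                c2 = int(rng.binomial(2, f))
                g[vid] = c2 if a2 == 1 else 2 - c2
            samples.append(f"anc{idx:04d}")
            ages.append(age)
            genos.append(g)
            idx += 1
    return AncientSampleTable(samples, ages, genos)
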
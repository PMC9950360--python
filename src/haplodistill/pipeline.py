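"""End-to-end orchestration: fixtures, configuration and the full analysis.

``run_all`` wires the stages together on whatever inputs the config names:
LD block delineation -> clade distillation -> sliding diversity scan with a
simulated Tajima's D null -> archaic concordance and dating -> expected
block length -> cis-eQTL regression.  Stages whose inputs are absent are
skipped with an explicit notice; any stage error aborts with the stage
name.  Identical config + seed gives byte-identical outputs.

``make_fixtures`` writes a complete synthetic bundle (two-clade VCF, panel,
archaic, outgroup, ancient and expression tables plus ground truth) that
exercises every stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import archaic as archaic_mod
from . import coalsim, distill, eqtl, io, ld, scan
from .datatypes import DataError, HaplotypeMatrix

STAGES = ("ld", "distill", "scan", "archaic", "eqtl")


@dataclass
class PipelineConfig:
    vcf: str = ""
    panel: str = ""
    archaic: str = ""  # may list several comma-separated tables
    outgroup: str = ""
    ancient: str = ""
    expression: str = ""
    region: str = ""
    tag_vid: str = ""
    ancient_tags: str = ""  # comma-separated tag vids for the trajectory
    ld_threshold: float = 0.8
    window_size: int = 1500
    step: int = 100
    n_null: int = 1000
    n_boot: int = 100
    calibration_years: float = 6.0e6
    gen_time: float = 25.0
    rec_rate: float = 0.62
    seed: int = 0

    def validate(self) -> None:
        if self.ld_threshold <= 0 or self.window_size <= 0 or self.step <= 0:
            raise DataError("thresholds and window geometry must be positive")
        if not self.vcf:
            raise DataError("config must name a vcf")


_FLOAT_KEYS = {"ld_threshold", "calibration_years", "gen_time", "rec_rate"}
_INT_KEYS = {"window_size", "step", "n_null", "n_boot", "seed"}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a flat key=value config file (``#`` comments allowed)."""
    cfg = PipelineConfig()
    base = Path(path).parent
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise DataError(f"{path} line {ln}: expected key=value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if not hasattr(cfg, key):
            raise DataError(f"{path} line {ln}: unknown key {key!r}")
        if key in _FLOAT_KEYS:
            setattr(cfg, key, float(value))
        elif key in _INT_KEYS:
            setattr(cfg, key, int(value))
        else:
            if key in ("vcf", "panel", "archaic", "outgroup", "ancient", "expression"):
                value = ",".join(
                    str((base / v).resolve()) if v and not Path(v).is_absolute() else v
                    for v in value.split(",")
                    if v
                )
            setattr(cfg, key, value)
    return cfg


def _read_outgroup(path: str | Path, matrix: HaplotypeMatrix) -> np.ndarray:
    """Read an outgroup base per position (TSV pos, base) and align it to the
    matrix variants as 0/1 (NaN where no call or a third allele)."""
    calls: dict[int, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("pos"):
            continue
        parts = line.split()
        calls[int(parts[0])] = parts[1].upper()
    out = np.full(matrix.n_variants, np.nan)
    for i, v in enumerate(matrix.variants):
        base = calls.get(v.pos)
        if base == v.ref_allele:
            out[i] = 0.0
        elif base == v.alt_allele:
            out[i] = 1.0
    return out


def write_outgroup(matrix: HaplotypeMatrix, alleles: np.ndarray, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("pos\tbase\n")
        for v, a in zip(matrix.variants, alleles):
            base = v.alt_allele if a == 1 else v.ref_allele
            fh.write(f"{v.pos}\t{base}\n")


@dataclass
class PipelineReport:
    lines: list[str] = field(default_factory=list)
    results: dict = field(default_factory=dict)

    def add(self, text: str = "") -> None:
        self.lines.append(text)

    def text(self) -> str:
        return "\n".join(self.lines) + "\n"


def run_all(config: PipelineConfig, out_dir: str | Path) -> PipelineReport:
    """Execute every stage whose inputs are present; write TSVs, newick and
    a summary report under ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rep = PipelineReport()
    path_keys = {"vcf", "panel", "archaic", "outgroup", "ancient", "expression"}
    cfg_text = "\n".join(
        f"{k}={getattr(config, k)}"
        for k in sorted(vars(config))
        if k not in path_keys
    )
    rep.add("haplodistill pipeline report")
    rep.add(f"config_hash={hashlib.sha256(cfg_text.encode()).hexdigest()[:16]}")
    rep.add()

    def stage_error(name: str, exc: Exception) -> Exception:
        return DataError(f"stage {name!r} failed: {exc}")

    # ---- input stage -------------------------------------------------
    try:
        matrix = io.read_vcf(config.vcf, region=config.region or None)
        if config.panel:
            pop, superpop = io.read_panel(config.panel)
            matrix.population.update(pop)
            matrix.superpopulation.update(superpop)
    except Exception as exc:
        raise stage_error("io", exc)
    rep.add(f"input: {matrix.n_variants} variants x {matrix.n_haplotypes} haplotypes")

    # ---- LD block ----------------------------------------------------
    try:
        tag = config.tag_vid or matrix.variants[matrix.n_variants // 2].vid
        block = ld.ld_block_from_tag(matrix, tag, threshold=config.ld_threshold)
    except Exception as exc:
        raise stage_error("ld", exc)
    block_df = pd.DataFrame(
        {
            "vid": [v.vid for v in matrix.variants],
            "pos": matrix.positions,
            "r2_with_tag": [
                block.r2_with_tag.get(v.vid, np.nan) for v in matrix.variants
            ],
            "in_block": [v.vid in set(block.member_vids) for v in matrix.variants],
        }
    )
    block_df.to_csv(out / "ld_block.tsv", sep="\t", index=False)
    rep.add(
        f"ld: tag={tag} threshold={config.ld_threshold} members={len(block.member_vids)}"
        f" span={block.span_start}-{block.span_end} ({block.span_bp/1000:.1f} kb)"
    )

    # ---- clade distillation ------------------------------------------
    try:
        block_matrix = matrix.subset_rows(
            [i for i, v in enumerate(matrix.variants) if v.vid in set(block.member_vids)]
        )
        outgroup_vec = outgroup_full = None
        if config.outgroup:
            outgroup_full = _read_outgroup(config.outgroup, matrix)
            keep = [
                i for i, v in enumerate(matrix.variants)
                if v.vid in set(block.member_vids)
            ]
            outgroup_vec = outgroup_full[keep]
            assignment = distill.assign_clades(
                block_matrix, method="nj_root_split", outgroup_sequence=outgroup_vec
            )
        else:
            assignment = distill.assign_clades(block_matrix, method="kmeans2")
        support = distill.bootstrap_bipartition(
            block_matrix,
            assignment,
            outgroup_sequence=outgroup_vec,
            n_reps=config.n_boot,
            seed=config.seed,
        )
        core = distill.core_haplotypes(block_matrix, assignment)
        tree = distill.nj_tree(
            distill.hamming_distances(
                block_matrix,
                extra_sequences={"outgroup": outgroup_vec}
                if outgroup_vec is not None
                else None,
            )
        )
        (out / "tree.nwk").write_text(
            tree.newick("outgroup" if outgroup_vec is not None else None) + "\n"
        )
        freqs = None
        if matrix.population:
            freqs = distill.clade_frequencies(block_matrix, assignment)
            freqs.per_population.to_csv(out / "clade_frequencies.tsv", sep="\t", index=False)
    except Exception as exc:
        raise stage_error("distill", exc)
    core.to_csv(out / "core_haplotypes.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(assignment.assignment.items()), columns=["haplotype", "clade"]
    ).to_csv(out / "clade_assignment.tsv", sep="\t", index=False)
    sizes = assignment.clade_sizes()
    rep.add(
        f"distill: method={assignment.method} clade1={sizes[1]} clade2={sizes[2]}"
        f" ambiguous={len(assignment.ambiguous)}"
        f" bootstrap_support={support.support}/{support.n_reps}"
    )
    if freqs is not None:
        rep.add(
            f"distill: clade2 overall frequency {freqs.overall_pct:.1f}%"
            f" (unweighted mean across populations;"
            f" haplotype-weighted {freqs.overall_weighted_pct:.1f}%)"
        )

    # ---- ancient trajectory ------------------------------------------
    if config.ancient:
        try:
            ancient = io.read_ancient(config.ancient)
            if config.ancient_tags:
                tags = [t for t in config.ancient_tags.split(",") if t]
            else:
                in_core = set(core["vid"])
                tags = sorted(
                    {vid for g in ancient.genotypes for vid in g} & in_core
                )
            traj = distill.temporal_trajectory(ancient, core, tags)
            traj.to_csv(out / "temporal_trajectory.tsv", sep="\t", index=False)
            occupied = traj.dropna(subset=["clade2_freq_pct"])
            rep.add(
                f"ancient: {len(ancient)} samples, {len(tags)} tag SNPs,"
                f" mean frequency over occupied bins"
                f" {occupied['clade2_freq_pct'].mean():.1f}%"
            )
        except Exception as exc:
            raise stage_error("ancient", exc)
    else:
        rep.add("ancient: skipped (no ancient-sample table)")

    # ---- sliding scan + null -----------------------------------------
    try:
        pos = matrix.positions
        region = (int(pos[0]), int(pos[-1]))
        window_scan = scan.sliding_scan(
            matrix, region, window_size=config.window_size, step=config.step
        )
        window_scan.windows.to_csv(out / "scan.tsv", sep="\t", index=False)
        ranked = scan.rank_windows(window_scan)
        peak = ranked.ranked.iloc[0]
        null = coalsim.neutral_replicates(
            n=matrix.n_haplotypes,
            S_fixed=int(peak["S"]),
            n_reps=config.n_null,
            seed=config.seed + 1,
        )
        p_emp = scan.empirical_p(float(peak["tajima_d"]), null["D"])
    except Exception as exc:
        raise stage_error("scan", exc)
    rep.add(
        f"scan: {len(window_scan.windows)} windows of {config.window_size} bp"
        f" step {config.step} bp"
    )
    rep.add(
        f"scan: peak segment {ranked.top_segment[0]}-{ranked.top_segment[1]}"
        f" pi={peak['pi_per_site']:.5f} D={peak['tajima_d']:.2f}"
        f" empirical_p={p_emp:.4g} (fixed-S null, {config.n_null} reps)"
        + (" [tied]" if ranked.tied else "")
    )

    # ---- archaic concordance + dating + block length ------------------
    hap_ids = block_matrix.haplotype_ids
    c1 = [j for j, h in enumerate(hap_ids) if assignment.assignment.get(h) == 1]
    c2 = [j for j, h in enumerate(hap_ids) if assignment.assignment.get(h) == 2]
    t_est = None
    if config.outgroup:
        try:
            # date on the full locus: restricting to block members would
            # over-represent clade-defining sites relative to the calibration
            g1 = matrix.alleles[:, c1].astype(float).T
            g2 = matrix.alleles[:, c2].astype(float).T
            g1[g1 < 0] = np.nan
            g2[g2 < 0] = np.nan
            dating = archaic_mod.date_divergence(
                g1, g2, outgroup_full, T_calibration_years=config.calibration_years
            )
            t_est = dating.t_years
            rep.add(
                f"dating: clade1-clade2 divergence {t_est/1e6:.2f} My"
                f" (d_focal={dating.d_focal:.1f}, d_cal={dating.d_calibration:.1f},"
                f" calibration {config.calibration_years/1e6:.0f} My)"
            )
        except Exception as exc:
            raise stage_error("dating", exc)
    else:
        rep.add("dating: skipped (no outgroup sequence)")

    if config.archaic:
        try:
            for path in config.archaic.split(","):
                table = io.read_archaic(path)
                report = archaic_mod.concordance(core, table, reference_clade=2)
                rep.add(
                    f"archaic: {report.individual_id}: {report.n_hom_match}/"
                    f"{report.n_hom} homozygous sites match clade 2"
                    f" ({report.pct_hom_match}%), {report.n_het} het site(s)"
                    f" of which {report.n_het_sharing} share an allele"
                )
        except Exception as exc:
            raise stage_error("archaic", exc)
    else:
        rep.add("archaic: skipped (no archaic genotype table)")

    t_for_block = t_est if t_est else 1.54e6
    blen = archaic_mod.expected_block_length(
        t_for_block, config.gen_time, config.rec_rate
    )
    rep.add(
        f"block length: expected {blen:.0f} bp ({blen/1000:.2f} kb) for a"
        f" {t_for_block/1e6:.2f} My haplotype at {config.rec_rate} cM/Mb,"
        f" observed block span {block.span_bp/1000:.1f} kb"
    )

    # ---- eQTL ---------------------------------------------------------
    if config.expression:
        try:
            expr = io.read_expression(config.expression)
            dosages, dropped = eqtl.dosage_code(block_matrix, assignment)
            fit = eqtl.fit_additive(dosages, expr)
            rep.add(
                f"eqtl: beta={fit.beta:.3f} se={fit.se:.3f} r2={fit.r_squared:.3f}"
                f" p={fit.p:.3g} n={fit.n}"
                + (f" ({len(dropped)} sample(s) dropped)" if dropped else "")
            )
        except Exception as exc:
            raise stage_error("eqtl", exc)
    else:
        rep.add("eqtl: skipped (no expression table)")

    (out / "report.txt").write_text(rep.text())
    return rep


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

#: fixture geometry: a 70 kb locus on build-37-like coordinates with a dense
#: 3 kb central target, 135 + 65 haplotypes (clade 2 at 32.5%)
FIXTURE_REGION_START = 70_361_741
FIXTURE_L = 70_000
FIXTURE_POPS = ("POP1", "POP2", "POP3", "POP4")
FIXTURE_SUPERPOPS = {"POP1": "AFR", "POP2": "EUR", "POP3": "EAS", "POP4": "AMR"}


def make_fixtures(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write the default synthetic bundle plus ground truth and a run config.

    Returns a mapping of logical names to file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = coalsim.SimParams(
        seed=seed,
        L=FIXTURE_L,
        region_start=FIXTURE_REGION_START,
    )
    sim = coalsim.simulate_two_clade(params)
    matrix = sim.matrix

    # population panel: round-robin over the shuffled diploid samples
    samples = list(dict.fromkeys(matrix.sample_ids))
    pop = {s: FIXTURE_POPS[i % len(FIXTURE_POPS)] for i, s in enumerate(samples)}
    matrix.population.update(pop)
    matrix.superpopulation.update(FIXTURE_SUPERPOPS)

    paths = {
        "vcf": out / "haplotypes.vcf",
        "panel": out / "panel.tsv",
        "archaic": out / "archaic.tsv",
        "outgroup": out / "outgroup.tsv",
        "ancient": out / "ancient.tsv",
        "expression": out / "expression.tsv",
        "truth": out / "truth.json",
        "config": out / "run.cfg",
    }
    io.write_vcf(matrix, paths["vcf"])
    with paths["panel"].open("w") as fh:
        fh.write("sample\tpopulation\tsuperpopulation\n")
        for s in samples:
            fh.write(f"{s}\t{pop[s]}\t{FIXTURE_SUPERPOPS[pop[s]]}\n")
    io.write_archaic(sim.archaic, paths["archaic"])
    write_outgroup(matrix, sim.outgroup, paths["outgroup"])

    # clade-2 orientation of the clade-defining (stem) variants
    labels = sim.truth.clade_labels
    hap_ids = matrix.haplotype_ids
    c2_cols = [j for j, h in enumerate(hap_ids) if labels[h] == 2]
    stem_set = set(sim.truth.stem_positions)
    stem_variants = [
        (i, v) for i, v in enumerate(matrix.variants) if v.pos in stem_set
    ]
    tag_orient = {}
    for i, v in stem_variants:
        freq2 = matrix.alleles[i, c2_cols].mean()
        tag_orient[v.vid] = 1 if freq2 > 0.5 else 0

    # tag SNP for LD / eQTL: the stem variant closest to the target centre
    centre = sum(sim.truth.target_segment) // 2
    tag_vid = min(stem_variants, key=lambda iv: abs(iv[1].pos - centre))[1].vid

    # 15 trajectory tags spread across the stem variants
    stem_vids = [v.vid for _, v in stem_variants]
    step = max(1, len(stem_vids) // 15)
    traj_tags = stem_vids[::step][:15]
    ancient = coalsim.simulate_ancient_samples(
        freq_by_age=lambda age: 0.30,
        tag_clade2_allele={t: tag_orient[t] for t in traj_tags},
        n_per_bin=10,
        missing_rate=0.2,
        seed=seed + 11,
    )
    io.write_ancient(ancient, traj_tags, paths["ancient"])

    # expression with variance explained 0.235 at clade-2 frequency 0.325
    dosages = {}
    for k, s in enumerate(samples):
        h1, h2 = hap_ids[2 * k], hap_ids[2 * k + 1]
        dosages[s] = (labels[h1] == 2) + (labels[h2] == 2)
    beta = coalsim.beta_for_r2(0.235, sigma=1.0, clade2_freq=0.325)
    expr = coalsim.simulate_expression(dosages, beta=beta, sigma=1.0, seed=seed + 13)
    io.write_expression(expr, paths["expression"])

    paths["truth"].write_text(
        json.dumps(
            {
                "seed": seed,
                "clade_labels": labels,
                "stem_positions": sim.truth.stem_positions,
                "tmrca1_gens": sim.truth.tmrca1_gens,
                "tmrca2_gens": sim.truth.tmrca2_gens,
                "rejections": sim.truth.rejections,
                "target_segment": list(sim.truth.target_segment),
                "tag_vid": tag_vid,
                "trajectory_tags": traj_tags,
                "expression_beta": beta,
            },
            indent=1,
            sort_keys=True,
        )
        + "\n"
    )
    paths["config"].write_text(
        "\n".join(
            [
                f"vcf={paths['vcf'].name}",
                f"panel={paths['panel'].name}",
                f"archaic={paths['archaic'].name}",
                f"outgroup={paths['outgroup'].name}",
                f"ancient={paths['ancient'].name}",
                f"expression={paths['expression'].name}",
                f"tag_vid={tag_vid}",
                "ld_threshold=0.8",
                "window_size=1500",
                "step=100",
                "n_null=1000",
                "n_boot=100",
                "calibration_years=6e6",
                "gen_time=25",
                "rec_rate=0.62",
                f"seed={seed}",
            ]
        )
        + "\n"
    )
    return paths
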
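"""File formats, configuration and the end-to-end pipeline driver.

Conventions: internal coordinates are 1-based inclusive (as in the result
tables); emitted BED is 0-based half-open.  VCF is read with cyvcf2;
multiallelic records are skipped with a logged count, and records whose
child minor-allele frequency falls below the MAF filter (default 5%) are
dropped -- low-frequency variants can produce chance parent-of-origin
signal from a handful of heterozygotes.  Phased child VCFs declare their
allele-order convention (``paternal_first`` by default) since VCF itself
does not standardize parental order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConsistencyError, InputError
from .simdata import (
    COVARIATE_COLUMNS,
    CovariateSet,
    MethylationMatrix,
    SnpPanelSpec,
    TruthRecord,
    simulate_covariates,
    simulate_duo_genotypes,
    simulate_methylation,
)
from .transmission import MISSING, GenotypeDuoSet, build_codes

logger = logging.getLogger("poemeth")

__all__ = [
    "PipelineConfig",
    "read_duo_vcf",
    "read_methylation_matrix",
    "read_bed",
    "write_bed",
    "read_covariates_tsv",
    "load_config",
    "run_pipeline",
]


# ---------------------------------------------------------------- writers

def _vcf_header(duos: GenotypeDuoSet, samples: list[str]) -> str:
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for c in pd.unique(duos.snp_meta["chrom"]):
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    return "\n".join(lines) + "\n"


def write_child_vcf(duos: GenotypeDuoSet, path: str | Path) -> Path:
    """Phased child VCF with paternal|maternal allele order."""
    if duos.child_phase is None:
        raise InputError("duo set carries no phase information")
    path = Path(path)
    meta = duos.snp_meta
    minor_is_alt = (meta["minor_allele"] == meta["alt"]).to_numpy()
    with path.open("w") as fh:
        fh.write(_vcf_header(duos, duos.samples))
        for j, row in enumerate(meta.itertuples(index=False)):
            gts = []
            for i in range(duos.n_duos):
                pat, mat = duos.child_phase[i, j]
                if pat == MISSING or mat == MISSING:
                    gts.append(".|.")
                else:
                    if minor_is_alt[j]:
                        a, b = int(pat), int(mat)
                    else:
                        a, b = 1 - int(pat), 1 - int(mat)
                    gts.append(f"{a}|{b}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    return path


def write_mother_vcf(duos: GenotypeDuoSet, path: str | Path) -> Path:
    """Unphased mother VCF (mother sample ids are ``M_<child id>``)."""
    path = Path(path)
    meta = duos.snp_meta
    minor_is_alt = (meta["minor_allele"] == meta["alt"]).to_numpy()
    mothers = [f"M_{s}" for s in duos.samples]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with path.open("w") as fh:
        fh.write(_vcf_header(duos, mothers))
        for j, row in enumerate(meta.itertuples(index=False)):
            gts = []
            for i in range(duos.n_duos):
                g = int(duos.mother[i, j])
                if g == MISSING:
                    gts.append("./.")
                else:
                    alt_count = g if minor_is_alt[j] else 2 - g
                    gts.append(gt_map[alt_count])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    return path


def write_ped(duos: GenotypeDuoSet, covs: CovariateSet | None, path: str | Path) -> Path:
    """Six-column PED linking each child to its mother."""
    path = Path(path)
    sex = None
    if covs is not None:
        sex = covs.table["sex"].to_numpy()
    with path.open("w") as fh:
        for i, child in enumerate(duos.samples):
            mother = f"M_{child}"
            child_sex = int(sex[i]) + 1 if sex is not None else 0  # PED: 1 male, 2 female
            fh.write(f"F{i + 1}\t{mother}\t0\t0\t2\t-9\n")
            fh.write(f"F{i + 1}\t{child}\t0\t{mother}\t{child_sex}\t-9\n")
    return path


def write_methylation_tsv(mm: MethylationMatrix, path: str | Path) -> Path:
    path = Path(path)
    out = mm.values.copy()
    out.index.name = "cpg_id"
    out.to_csv(path, sep="\t", float_format="%.6g")
    return path


def write_cpg_bed(mm: MethylationMatrix, path: str | Path) -> Path:
    """CpG coordinates as 0-based half-open BED."""
    path = Path(path)
    bed = pd.DataFrame(
        {
            "chrom": mm.coords["chrom"],
            "start": mm.coords["pos"] - 1,
            "end": mm.coords["pos"],
            "name": mm.coords["cpg_id"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
    return path


def write_covariates_tsv(covs: CovariateSet, path: str | Path) -> Path:
    path = Path(path)
    out = covs.table.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format="%.6g")
    return path


def write_bed(regions: pd.DataFrame, path: str | Path) -> Path:
    """Write 1-based inclusive regions as 0-based half-open BED."""
    path = Path(path)
    bed = regions.copy()
    bed["start"] = bed["start"] - 1
    cols = ["chrom", "start", "end"] + [c for c in bed.columns if c not in ("chrom", "start", "end")]
    bed[cols].to_csv(path, sep="\t", header=False, index=False)
    return path


# ---------------------------------------------------------------- readers

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED (0-based half-open) into 1-based inclusive chrom/start/end."""
    try:
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise InputError(f"malformed BED {path}: {exc}") from exc
    if bed.shape[1] < 3:
        raise InputError(f"malformed BED {path}: fewer than 3 columns")
    out = bed.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    if not (np.issubdtype(out["start"].dtype, np.number) and np.issubdtype(out["end"].dtype, np.number)):
        raise InputError(f"malformed BED {path}: non-numeric coordinates")
    out["chrom"] = out["chrom"].astype(str)
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    if bed.shape[1] > 3:
        out["name"] = bed.iloc[:, 3]
    return out


def _read_ped_links(path: str | Path) -> dict[str, str]:
    """child id -> mother id from a 6-column PED."""
    ped = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"])
    return {
        str(r.iid): str(r.mother)
        for r in ped.itertuples(index=False)
        if str(r.mother) != "0"
    }


def read_duo_vcf(
    child_vcf: str | Path,
    mother_vcf: str | Path,
    ped: str | Path,
    maf_min: float = 0.05,
    phase_convention: str = "paternal_first",
) -> GenotypeDuoSet:
    """Load duo genotypes from child + mother VCFs linked by a PED file.

    Minor alleles are determined from the children (ties at 0.5 broken to
    the alt allele); records with child MAF below ``maf_min`` or with more
    than one alt allele are dropped with logged counts.  Phased child
    genotypes are preserved with the declared parental allele order.
    """
    from cyvcf2 import VCF

    if phase_convention not in ("paternal_first", "maternal_first"):
        raise InputError("phase_convention must be paternal_first or maternal_first")
    links = _read_ped_links(ped)
    child_reader = VCF(str(child_vcf))
    mother_reader = VCF(str(mother_vcf))
    children = list(child_reader.samples)
    unknown = [c for c in children if c not in links]
    if unknown:
        raise InputError(f"child samples missing from PED: {unknown[:5]}")
    mother_order = [links[c] for c in children]
    mother_samples = list(mother_reader.samples)
    missing_mothers = [m for m in mother_order if m not in mother_samples]
    if missing_mothers:
        raise InputError(f"mothers missing from mother VCF: {missing_mothers[:5]}")
    mother_idx = np.array([mother_samples.index(m) for m in mother_order])

    child_alt, child_pat, child_mat, mother_alt, meta_rows = [], [], [], [], []
    n_multi = 0
    mother_variants = {(v.CHROM, v.POS, v.REF, ",".join(v.ALT)): v.genotype.array()
                       for v in mother_reader}
    for v in child_reader:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        key = (v.CHROM, v.POS, v.REF, ",".join(v.ALT))
        if key not in mother_variants:
            logger.warning("SNP %s:%s absent from mother VCF; skipped", v.CHROM, v.POS)
            continue
        garr = v.genotype.array()  # (n, 3): allele1, allele2, phased
        a1, a2, phased = garr[:, 0], garr[:, 1], garr[:, 2].astype(bool)
        alt = np.where((a1 < 0) | (a2 < 0), MISSING, a1 + a2).astype(np.int8)
        pat = np.where(phased & (a1 >= 0), a1, MISSING).astype(np.int8)
        mat = np.where(phased & (a2 >= 0), a2, MISSING).astype(np.int8)
        if phase_convention == "maternal_first":
            pat, mat = mat, pat
        marr = mother_variants[key][mother_idx]
        m_alt = np.where((marr[:, 0] < 0) | (marr[:, 1] < 0), MISSING,
                         marr[:, 0] + marr[:, 1]).astype(np.int8)
        child_alt.append(alt)
        child_pat.append(pat)
        child_mat.append(mat)
        mother_alt.append(m_alt)
        meta_rows.append((v.ID or f"{v.CHROM}:{v.POS}", v.CHROM, v.POS, v.REF, v.ALT[0]))
    if n_multi:
        logger.info("skipped %d multiallelic records", n_multi)
    if not meta_rows:
        raise InputError("no usable biallelic records shared by both VCFs")
    child_alt = np.column_stack(child_alt)
    child_pat = np.column_stack(child_pat)
    child_mat = np.column_stack(child_mat)
    mother_alt = np.column_stack(mother_alt)
    meta = pd.DataFrame(meta_rows, columns=["id", "chrom", "pos", "ref", "alt"])
    # minor allele from children; ties at 0.5 broken to alt
    masked = np.ma.masked_equal(child_alt, MISSING)
    alt_freq = np.asarray(masked.mean(axis=0) / 2.0)
    minor_is_alt = alt_freq <= 0.5
    maf = np.where(minor_is_alt, alt_freq, 1 - alt_freq)
    meta["minor_allele"] = np.where(minor_is_alt, meta["alt"], meta["ref"])
    meta["maf"] = maf
    # convert alt counts to minor counts
    def to_minor(mat_counts):
        out = np.where(minor_is_alt[None, :], mat_counts, 2 - mat_counts)
        return np.where(mat_counts == MISSING, MISSING, out).astype(np.int8)

    child_minor = to_minor(child_alt)
    mother_minor = to_minor(mother_alt)
    pat_minor = np.where(child_pat == MISSING, MISSING,
                         np.where(minor_is_alt[None, :], child_pat, 1 - child_pat)).astype(np.int8)
    mat_minor = np.where(child_mat == MISSING, MISSING,
                         np.where(minor_is_alt[None, :], child_mat, 1 - child_mat)).astype(np.int8)
    keep = maf >= maf_min
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d records with child MAF < %.3f", dropped, maf_min)
    phase = np.stack([pat_minor[:, keep], mat_minor[:, keep]], axis=2)
    if np.all(phase == MISSING):
        phase = None
    return GenotypeDuoSet(
        samples=children,
        child=child_minor[:, keep],
        mother=mother_minor[:, keep],
        snp_meta=meta.loc[keep].reset_index(drop=True),
        child_phase=phase,
    )


def read_methylation_matrix(
    tsv: str | Path,
    cpg_bed: str | Path,
    samples: list[str] | None = None,
    time_point: str = "",
) -> MethylationMatrix:
    """Read a CpG x sample TSV of beta values plus a CpG coordinate BED.

    Values must be in [0, 1] or missing; out-of-range entries raise with the
    offending CpG/sample named.  When ``samples`` is given, columns are
    intersected with it and reordered to match; CpGs absent from the BED are
    excluded with a warning.
    """
    vals = pd.read_csv(tsv, sep="\t", index_col=0)
    vals.index = vals.index.astype(str)
    arr = vals.to_numpy(dtype=float)
    bad = np.argwhere((arr < 0) | (arr > 1))
    if bad.size:
        i, j = bad[0]
        raise InputError(
            f"beta value out of [0, 1] at CpG {vals.index[i]!r}, sample "
            f"{vals.columns[j]!r}: {arr[i, j]}"
        )
    bed = read_bed(cpg_bed)
    if "name" not in bed.columns:
        raise InputError("CpG BED needs a 4th (name) column with CpG ids")
    coords = pd.DataFrame(
        {"cpg_id": bed["name"].astype(str), "chrom": bed["chrom"], "pos": bed["end"]}
    )
    known = set(coords["cpg_id"])
    missing = [c for c in vals.index if c not in known]
    if missing:
        logger.warning("%d CpGs absent from BED excluded (e.g. %s)", len(missing), missing[:3])
        vals = vals.loc[[c for c in vals.index if c in known]]
    coords = coords[coords["cpg_id"].isin(vals.index)].reset_index(drop=True)
    if samples is not None:
        shared = [s for s in samples if s in vals.columns]
        if not shared:
            raise ConsistencyError("no shared samples between methylation and genotypes")
        if len(shared) < len(samples):
            logger.warning("%d genotyped samples lack methylation", len(samples) - len(shared))
        vals = vals[shared]
    return MethylationMatrix(values=vals, coords=coords, time_point=time_point)


def read_covariates_tsv(path: str | Path, samples: list[str] | None = None) -> CovariateSet:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    if samples is not None:
        missing = [s for s in samples if s not in table.index]
        if missing:
            raise ConsistencyError(f"samples missing from covariates: {missing[:5]}")
        table = table.loc[samples]
    return CovariateSet(samples=list(table.index), table=table)


# ------------------------------------------------------------- pipeline

@dataclass
class PipelineConfig:
    """Configuration of the full scan pipeline (YAML key-value file)."""

    out_dir: str = "poemeth_out"
    seed: int = 1
    window: int = 500_000
    se_type: str = "HC3"
    min_het: int = 3
    alpha: float = 0.05
    min_sep: int = 2_000_000
    flank: int = 2_000_000
    alpha_pattern: float = 0.05
    min_group: int = 5
    phase_convention: str = "paternal_first"
    maf_min: float = 0.05
    meff_method: str = "li_ji"
    time_points: list[str] = field(default_factory=lambda: ["childhood"])
    # either simulate...
    simulate: dict | None = None
    # ...or read from files
    child_vcf: str | None = None
    mother_vcf: str | None = None
    ped: str | None = None
    methylation: dict[str, str] | None = None  # time point -> TSV path
    cpg_bed: str | None = None
    covariates: str | None = None
    known_regions: str | None = None

    def __post_init__(self) -> None:
        if self.window <= 0 or self.min_sep <= 0 or self.flank < 0:
            raise InputError("window/min_sep must be positive, flank non-negative")
        if self.phase_convention not in ("paternal_first", "maternal_first"):
            raise InputError("phase_convention must be paternal_first or maternal_first")


def load_config(path: str | Path) -> PipelineConfig:
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**raw)
    if cfg.simulate is None:
        for key in ("child_vcf", "mother_vcf", "ped", "methylation", "cpg_bed"):
            val = getattr(cfg, key)
            if val is None:
                raise InputError(f"config lacks {key!r} (and no simulate block)")
        for p in [cfg.child_vcf, cfg.mother_vcf, cfg.ped, cfg.cpg_bed] + list(
            (cfg.methylation or {}).values()
        ):
            if not Path(p).exists():
                raise InputError(f"input path does not exist: {p}")
    return cfg


def _simulated_inputs(cfg: PipelineConfig):
    sim = dict(cfg.simulate or {})
    rng_seq = np.random.SeedSequence(cfg.seed)
    s_geno, s_cov, s_meth = rng_seq.spawn(3)
    spec = SnpPanelSpec(
        n_snps=int(sim.get("n_snps", 60)),
        maf=sim.get("maf", 0.25),
        spacing=int(sim.get("spacing", 700_000)),
    )
    duos, _ = simulate_duo_genotypes(spec, int(sim.get("n_duos", 200)), s_geno)
    truth = []
    patterns = sim.get("patterns", ["uniparental_maternal", "bipolar", "null"])
    poe_r2 = float(sim.get("poe_r2", 0.1))
    n_cpgs = int(sim.get("n_cpgs", 30))
    snp_ids = list(duos.snp_meta["id"])
    for i in range(n_cpgs):
        pattern = patterns[i % len(patterns)]
        truth.append(
            TruthRecord(
                cpg_id=f"cg{i + 1:05d}",
                target_snp=snp_ids[(i * 3) % len(snp_ids)],
                pattern=pattern,
                poe_r2=0.0 if pattern == "null" else poe_r2,
            )
        )
    covs_by_tp, meth_by_tp = {}, {}
    for k, tp in enumerate(cfg.time_points):
        covs_tp = simulate_covariates(duos.n_duos, s_cov.spawn(1)[0] if k else s_cov,
                                      time_point=tp, samples=duos.samples)
        covs_by_tp[tp] = covs_tp
        meth_by_tp[tp] = simulate_methylation(
            duos, truth, covs_tp, s_meth.spawn(1)[0] if k else s_meth, time_point=tp
        )
    return duos, covs_by_tp, meth_by_tp, truth


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute simulate/load -> codes -> scan -> threshold -> loci -> summary.

    Returns a dict of in-memory results; summary tables are also written
    under ``cfg.out_dir``.  Deterministic given the config and seed.
    """
    from . import loci as ploci
    from . import multitest, poescan

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.simulate is not None:
        duos, covs_by_tp, meth_by_tp, truth = _simulated_inputs(cfg)
        logger.info("simulated %d duos x %d SNPs", duos.n_duos, duos.n_snps)
    else:
        duos = read_duo_vcf(cfg.child_vcf, cfg.mother_vcf, cfg.ped,
                            maf_min=cfg.maf_min, phase_convention=cfg.phase_convention)
        covs = read_covariates_tsv(cfg.covariates, duos.samples) if cfg.covariates else None
        covs_by_tp = {tp: covs for tp in cfg.methylation}
        meth_by_tp = {
            tp: read_methylation_matrix(path, cfg.cpg_bed, duos.samples, time_point=tp)
            for tp, path in cfg.methylation.items()
        }
        truth = None
    codes = build_codes(duos)
    scan_cfg = poescan.ScanConfig(window=cfg.window, se_type=cfg.se_type, min_het=cfg.min_het)
    results = poescan.run_scan(meth_by_tp, codes,
                               next(iter(covs_by_tp.values())), scan_cfg, duos.snp_meta)
    n_tests = int((~results["degenerate"]).sum())
    logger.info("scan: %d tests (%d degenerate)", len(results), len(results) - n_tests)
    genos = np.where(duos.child == MISSING, np.nan, duos.child).astype(float)
    span = duos.snp_meta["pos"].max() - duos.snp_meta["pos"].min()
    try:
        ratio_est = multitest.estimate_genomewide_ratio(
            genos, duos.snp_meta["pos"].to_numpy(), cfg.seed,
            n_windows=min(100, max(10, duos.n_snps // 2)),
            window=min(1_000_000, max(10_000, int(span // 4))),
            method=cfg.meff_method,
        )
        ratio = ratio_est.ratio
    except Exception as exc:
        logger.warning("Meff ratio estimation failed (%s); using ratio=1", exc)
        ratio = 1.0
    threshold = multitest.bonferroni_threshold(max(1, n_tests), ratio, cfg.alpha)
    logger.info("Meff ratio %.3f -> threshold %.3g", ratio, threshold)
    sig = results[(~results["degenerate"]) & (results["p_P"] < threshold)]
    clusters = ploci.cluster_loci(sig, cfg.min_sep)
    if cfg.known_regions:
        ploci.annotate_known(clusters, read_bed(cfg.known_regions), cfg.flank)
    first_tp = next(iter(meth_by_tp))
    snp_idx = {s: j for j, s in enumerate(codes.snp_ids)}
    for cl in clusters:
        lead = cl.lead
        j = snp_idx[lead["snp_id"]]
        y = meth_by_tp[lead["time_point"] or first_tp].values.loc[lead["cpg_id"]].to_numpy(float)
        cl.pattern, cl.low_confidence = ploci.classify_pattern(
            y, codes.A[:, j], codes.P[:, j], cfg.alpha_pattern, cfg.min_group
        )
    summary = ploci.locus_table(clusters, results, snp_meta=duos.snp_meta)
    results.to_csv(out / "scan_results.tsv", sep="\t", index=False)
    summary.to_csv(out / "locus_summary.tsv", sep="\t", index=False)
    with (out / "threshold.txt").open("w") as fh:
        fh.write(f"n_tests\t{n_tests}\nmeff_ratio\t{ratio:.4f}\nthreshold\t{threshold:.6g}\n")
    return {
        "duos": duos,
        "codes": codes,
        "results": results,
        "threshold": threshold,
        "meff_ratio": ratio,
        "loci": clusters,
        "summary": summary,
        "truth": truth,
    }
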
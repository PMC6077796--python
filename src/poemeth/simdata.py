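"""Synthetic mother-child duo cohorts with planted imprinting signals.

Every downstream stage of the scan (transmission coding, robust regression,
multiple-testing correction, locus calling, methylation-based transmission
inference) is exercised against cohorts produced here, since the real
cohorts this design targets are access-controlled.

The generative model:

* **Genotypes.**  Mothers are drawn under Hardy-Weinberg equilibrium at each
  SNP; each child receives one maternal allele (chosen at random from the
  mother's two) and one paternal allele drawn from the population frequency
  (fathers are never observed in a duo design, so simulating them would add
  nothing).  The true parental origin of every child allele is recorded, so
  heterozygote orderings are exchangeable and, in expectation, balanced.
  Optional LD blocks use a Gaussian-copula haplotype model with
  equicorrelated latents thresholded at the allele frequency: only the
  correlation structure matters for the effective-number-of-tests stage.

* **Methylation.**  CpG beta values are simulated on the raw [0, 1] scale as
  a genotype-group mean plus (optionally heteroscedastic) Gaussian noise,
  then clipped.  Three parent-of-origin architectures are supported:
  ``uniparental_maternal`` / ``uniparental_paternal``, where methylation
  tracks a single parental allele (one heterozygote ordering shifts away
  from the homozygote baseline, the hallmark of one silenced chromosome),
  and ``bipolar``, where the two homozygotes coincide while the two
  heterozygote orderings deviate in opposite directions.  Effect sizes are
  calibrated from realized sample moments so the fraction of methylation
  variance explained by the true POE coding matches ``poe_r2``.

  Note that a pure uniparental architecture cannot put more than ~50% of the
  variance on the POE axis: the same allelic shift loads the additive and
  POE codings equally, so at ``poe_r2`` above ``h / (4 w (1 - w))`` (h = het
  fraction, w = frequency of the active-allele carriers) the request is
  infeasible and a :class:`~poemeth.exceptions.GenerationError` is raised.

* **Covariates.**  Sex (balanced Bernoulli), age (constant per time point
  plus jitter), 3 genotype ancestry PCs and 10 control-probe batch PCs,
  all standard normal; 15 columns in total, with optional planted effects
  on methylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .exceptions import ConsistencyError, GenerationError, SpecificationError
from .transmission import MISSING, GenotypeDuoSet, build_codes

__all__ = [
    "SnpPanelSpec",
    "TruthRecord",
    "CovariateSet",
    "MethylationMatrix",
    "simulate_duo_genotypes",
    "simulate_covariates",
    "simulate_methylation",
    "write_fixture",
]

#: covariate column order (15 columns)
COVARIATE_COLUMNS = ["sex", "age"] + [f"gpc{i}" for i in range(1, 4)] + [
    f"cpc{i}" for i in range(1, 11)
]

#: default age (years) per time point, mirroring a birth/childhood/adolescence design
TIME_POINT_AGES = {"birth": 0.0, "childhood": 7.5, "adolescence": 17.1}


@dataclass
class SnpPanelSpec:
    """Specification of a simulated SNP panel.

    ``maf`` may be a scalar (shared by all SNPs) or a per-SNP array; values
    must lie in [0.05, 0.5] (the scan's own MAF filter, which guards against
    low-frequency variants producing chance parent-of-origin effects).
    ``ld_blocks`` is an optional list of ``(block_size, r)`` tuples assigned
    to consecutive SNPs starting at the first; remaining SNPs are
    independent.  Positions are 1-based and strictly increasing within a
    chromosome.
    """

    n_snps: int
    maf: float | np.ndarray = 0.25
    chrom: str | np.ndarray = "1"
    pos: np.ndarray | None = None
    spacing: int = 5_000
    ld_blocks: list[tuple[int, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise SpecificationError("n_snps must be >= 1")
        self.maf = np.broadcast_to(np.asarray(self.maf, dtype=float), (self.n_snps,)).copy()
        if np.any(self.maf < 0.05) or np.any(self.maf > 0.5):
            raise SpecificationError("all MAFs must lie in [0.05, 0.5]")
        self.chrom = np.broadcast_to(np.asarray(self.chrom, dtype=object), (self.n_snps,)).copy()
        if self.pos is None:
            self.pos = np.arange(1, self.n_snps + 1) * self.spacing
        self.pos = np.asarray(self.pos, dtype=np.int64)
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise SpecificationError(f"positions not strictly increasing on chromosome {c}")
        if self.ld_blocks is not None:
            if sum(b for b, _ in self.ld_blocks) > self.n_snps:
                raise SpecificationError("ld_blocks cover more SNPs than the panel holds")
            for size, r in self.ld_blocks:
                if size < 1 or not (0.0 <= r <= 1.0):
                    raise SpecificationError("ld block must have size >= 1 and r in [0, 1]")

    def blocks(self) -> list[tuple[np.ndarray, float]]:
        """Partition of SNP indices into (indices, r) LD blocks (singletons r=0)."""
        out: list[tuple[np.ndarray, float]] = []
        start = 0
        for size, r in self.ld_blocks or []:
            out.append((np.arange(start, start + size), r))
            start += size
        for j in range(start, self.n_snps):
            out.append((np.array([j]), 0.0))
        return out


@dataclass
class TruthRecord:
    """Planted architecture of one simulated CpG.

    ``pattern`` is one of ``uniparental_maternal``, ``uniparental_paternal``,
    ``bipolar`` or ``null``; ``poe_r2`` is the fraction of methylation
    variance explained by the true POE coding (0 iff ``null``).
    """

    cpg_id: str
    target_snp: str
    pattern: str
    poe_r2: float
    noise_model: str = "homoscedastic"
    pos: int | None = None

    PATTERNS = ("uniparental_maternal", "uniparental_paternal", "bipolar", "null")

    def __post_init__(self) -> None:
        if self.pattern not in self.PATTERNS:
            raise SpecificationError(f"unknown pattern {self.pattern!r}")
        if (self.pattern == "null") != (self.poe_r2 == 0):
            raise SpecificationError("poe_r2 must be 0 iff pattern is null")
        if not (0 <= self.poe_r2 < 1):
            raise SpecificationError("poe_r2 must lie in [0, 1)")
        if self.noise_model not in ("homoscedastic", "heteroscedastic"):
            raise SpecificationError(f"unknown noise model {self.noise_model!r}")


@dataclass
class CovariateSet:
    """Cohort covariates: sex, age, 3 genotype PCs, 10 control-matrix PCs."""

    samples: list[str]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COVARIATE_COLUMNS if c not in self.table.columns]
        if missing:
            raise SpecificationError(f"covariate table lacks columns: {missing}")
        if self.table.isna().any().any():
            raise SpecificationError("covariate table contains missing values")

    @property
    def matrix(self) -> np.ndarray:
        return self.table[COVARIATE_COLUMNS].to_numpy(dtype=float)


@dataclass
class MethylationMatrix:
    """CpG x sample beta values with CpG coordinates and a time-point label."""

    values: pd.DataFrame  # index: cpg_id, columns: sample ids, beta in [0, 1]
    coords: pd.DataFrame  # columns: cpg_id, chrom, pos (1-based)
    time_point: str = "birth"
    clipping_rate: float = 0.0
    #: generator truth for simulated matrices: cpg_id, delta, betaP_true
    planted: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise SpecificationError("beta values must lie in [0, 1]")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.index)


def simulate_duo_genotypes(
    spec: SnpPanelSpec, n_duos: int, seed: int | np.random.SeedSequence
) -> tuple[GenotypeDuoSet, np.ndarray]:
    """Draw mother-child duo genotypes under HWE and random mating.

    Returns the duo set (with phased child genotypes carrying the true
    parental origin of every allele) and the true POE code matrix
    ``truth_P`` (float, {-1, 0, +1}; no missingness in simulation).
    """
    if n_duos < 1:
        raise SpecificationError("n_duos must be >= 1")
    rng = np.random.default_rng(seed)
    m = spec.n_snps
    mother_h1 = np.empty((n_duos, m), dtype=np.int8)
    mother_h2 = np.empty((n_duos, m), dtype=np.int8)
    father_h = np.empty((n_duos, m), dtype=np.int8)
    for idx, r in spec.blocks():
        thr = ndtri(spec.maf[idx])  # latent < thr -> minor allele
        for hap in (mother_h1, mother_h2, father_h):
            shared = rng.standard_normal((n_duos, 1))
            own = rng.standard_normal((n_duos, idx.size))
            latent = np.sqrt(r) * shared + np.sqrt(1.0 - r) * own
            hap[:, idx] = (latent < thr).astype(np.int8)
    # child: one maternal haplotype per duo per block, one paternal haplotype
    maternal = np.empty((n_duos, m), dtype=np.int8)
    for idx, _ in spec.blocks():
        pick = rng.integers(0, 2, size=n_duos).astype(bool)
        maternal[:, idx] = np.where(pick[:, None], mother_h1[:, idx], mother_h2[:, idx])
    child_phase = np.stack([father_h, maternal], axis=2)  # paternal first
    child = (father_h + maternal).astype(np.int8)
    mother = (mother_h1 + mother_h2).astype(np.int8)
    snp_meta = pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(m)],
            "chrom": spec.chrom,
            "pos": spec.pos,
            "ref": "A",
            "alt": "G",
            "minor_allele": "G",
            "maf": spec.maf,
        }
    )
    samples = [f"C{i + 1:05d}" for i in range(n_duos)]
    duos = GenotypeDuoSet(
        samples=samples, child=child, mother=mother, snp_meta=snp_meta, child_phase=child_phase
    )
    truth_P = np.where(child == 1, maternal.astype(float) - father_h.astype(float), 0.0)
    return duos, truth_P


def simulate_covariates(
    n: int,
    seed: int | np.random.SeedSequence,
    time_point: str = "childhood",
    age_jitter_sd: float = 0.25,
    samples: list[str] | None = None,
) -> CovariateSet:
    """Simulate the 15-column covariate set for ``n`` children."""
    if n < 1:
        raise SpecificationError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = [f"C{i + 1:05d}" for i in range(n)]
    age0 = TIME_POINT_AGES.get(time_point, 7.5)
    table = pd.DataFrame(index=samples)
    table["sex"] = rng.integers(0, 2, size=n).astype(float)
    table["age"] = age0 + rng.normal(0.0, age_jitter_sd, size=n)
    for i in range(1, 4):
        table[f"gpc{i}"] = rng.standard_normal(n)
    for i in range(1, 11):
        table[f"cpc{i}"] = rng.standard_normal(n)
    return CovariateSet(samples=list(samples), table=table)


def _group_indicator(truth: TruthRecord, duos: GenotypeDuoSet, j: int) -> np.ndarray:
    """Mean-structure regressor for one planted CpG (before scaling by delta)."""
    pat = duos.child_phase[:, j, 0].astype(float)
    mat = duos.child_phase[:, j, 1].astype(float)
    if truth.pattern == "uniparental_maternal":
        return mat  # methylation tracks the maternal allele
    if truth.pattern == "uniparental_paternal":
        return pat
    if truth.pattern == "bipolar":
        return np.where(pat + mat == 1, mat - pat, 0.0)  # the POE coding itself
    return np.zeros(duos.n_duos)


def simulate_methylation(
    duos: GenotypeDuoSet,
    truth: list[TruthRecord],
    covs: CovariateSet | None,
    seed: int | np.random.SeedSequence,
    baseline: float = 0.5,
    noise_sd: float = 0.08,
    cov_effect_sd: float = 0.006,
    time_point: str = "childhood",
    cpg_offset: int = 150,
) -> MethylationMatrix:
    """Simulate beta values for the planted CpG architectures.

    Effect sizes are calibrated from realized sample moments so that the
    variance explained by the true POE coding matches each record's
    ``poe_r2``; covariate effects (coefficients drawn once per CpG with
    scale ``cov_effect_sd``) are included in the total-variance budget.
    Values are clipped to [0, 1] and the clipping rate stored on the result.
    """
    rng = np.random.default_rng(seed)
    snp_index = {s: j for j, s in enumerate(duos.snp_meta["id"])}
    n = duos.n_duos
    covmat = covs.matrix if covs is not None else None
    if covs is not None and list(covs.samples) != list(duos.samples):
        raise ConsistencyError("covariate samples do not match duo samples")
    rows, coords, clipped, planted = [], [], 0, []
    truth_P_all = np.where(
        duos.child == 1,
        duos.child_phase[:, :, 1].astype(float) - duos.child_phase[:, :, 0].astype(float),
        0.0,
    )
    for rec in truth:
        if rec.target_snp not in snp_index:
            raise ConsistencyError(f"target SNP {rec.target_snp!r} not in duo set")
        j = snp_index[rec.target_snp]
        ind = _group_indicator(rec, duos, j)
        P = truth_P_all[:, j]
        cov_contrib = np.zeros(n)
        if covmat is not None and cov_effect_sd > 0:
            betas = rng.normal(0.0, cov_effect_sd, size=covmat.shape[1])
            betas[1] /= 10.0  # age is on a ~10x larger scale than the PCs
            cov_contrib = (covmat - covmat.mean(axis=0)) @ betas
        v0 = noise_sd**2 + cov_contrib.var()
        if rec.poe_r2 > 0:
            var_p = P.var()
            a = np.cov(ind, P, ddof=0)[0, 1] ** 2 / var_p if var_p > 0 else 0.0
            denom = a - rec.poe_r2 * ind.var()
            if denom <= 0:
                raise GenerationError(
                    f"{rec.cpg_id}: poe_r2={rec.poe_r2} infeasible for pattern "
                    f"{rec.pattern} at this MAF (max "
                    f"{a / ind.var() if ind.var() > 0 else 0:.3f})"
                )
            delta = np.sqrt(rec.poe_r2 * v0 / denom)
        else:
            delta = 0.0
        mu = baseline + delta * (ind - ind.mean()) + cov_contrib
        if rec.noise_model == "heteroscedastic":
            mu_c = np.clip(mu, 0.02, 0.98)
            scale = np.sqrt(mu_c * (1 - mu_c))
            sd_i = noise_sd * scale / np.sqrt(np.mean(scale**2))
        else:
            sd_i = np.full(n, noise_sd)
        y = mu + rng.normal(0.0, 1.0, size=n) * sd_i
        clipped += int(((y < 0) | (y > 1)).sum())
        rows.append(np.clip(y, 0.0, 1.0))
        pos = rec.pos if rec.pos is not None else int(duos.snp_meta["pos"].iloc[j]) + cpg_offset
        coords.append((rec.cpg_id, duos.snp_meta["chrom"].iloc[j], pos))
        # true POE coefficient implied by the mean structure: the uniparental
        # shift splits equally between the additive and POE codings
        beta_p_true = delta / 2.0 if rec.pattern.startswith("uniparental") else delta
        planted.append((rec.cpg_id, rec.target_snp, rec.pattern, delta, beta_p_true))
    values = pd.DataFrame(rows, index=[r.cpg_id for r in truth], columns=duos.samples)
    coords_df = pd.DataFrame(coords, columns=["cpg_id", "chrom", "pos"])
    return MethylationMatrix(
        values=values,
        coords=coords_df,
        time_point=time_point,
        clipping_rate=clipped / max(1, len(truth) * n),
        planted=pd.DataFrame(
            planted, columns=["cpg_id", "target_snp", "pattern", "delta", "betaP_true"]
        ),
    )


def write_fixture(
    duos: GenotypeDuoSet,
    methylation: MethylationMatrix | dict[str, MethylationMatrix],
    covs: CovariateSet,
    truth: list[TruthRecord],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a complete plain-text fixture (VCF/PED/TSV/BED) to ``out_dir``.

    The child VCF is phased with paternal|maternal allele order, so the
    truth transmissions are recoverable from the files alone.  Round-trips
    losslessly through :mod:`poemeth.io` readers.
    """
    from . import io as pio

    if list(covs.samples) != list(duos.samples):
        raise ConsistencyError("covariate samples do not match duo samples")
    meths = methylation if isinstance(methylation, dict) else {methylation.time_point: methylation}
    for mm in meths.values():
        if list(mm.values.columns) != list(duos.samples):
            raise ConsistencyError("methylation samples do not match duo samples")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["child_vcf"] = pio.write_child_vcf(duos, out / "child.vcf")
    paths["mother_vcf"] = pio.write_mother_vcf(duos, out / "mother.vcf")
    paths["ped"] = pio.write_ped(duos, covs, out / "duos.ped")
    for tp, mm in meths.items():
        paths[f"methylation_{tp}"] = pio.write_methylation_tsv(
            mm, out / f"methylation_{tp}.tsv"
        )
    any_mm = next(iter(meths.values()))
    paths["cpg_bed"] = pio.write_cpg_bed(any_mm, out / "cpgs.bed")
    paths["covariates"] = pio.write_covariates_tsv(covs, out / "covariates.tsv")
    truth_df = pd.DataFrame(
        [
            {
                "cpg_id": r.cpg_id,
                "target_snp": r.target_snp,
                "pattern": r.pattern,
                "poe_r2": r.poe_r2,
                "noise_model": r.noise_model,
            }
            for r in truth
        ]
    )
    paths["truth"] = out / "truth.tsv"
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    codes = build_codes(duos)
    trans = pd.DataFrame(codes.P, index=duos.samples, columns=codes.snp_ids)
    paths["transmissions"] = out / "transmissions.tsv"
    trans.to_csv(paths["transmissions"], sep="\t")
    return paths
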
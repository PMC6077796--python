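"""Resolution of parental allele origin in mother-child duos and POE design coding.

A heterozygous child carries one minor and one major allele; for an imprinting
scan we need to know which parent transmitted the minor allele.  With only the
mother genotyped, Mendelian logic resolves this whenever the mother is
homozygous: her transmitted allele is then known with certainty, and the
child's other allele must be paternal.  Double-heterozygous duos are left
missing (LD-based phasing is out of scope here); missingness costs power but
cannot inflate the type-I error of the downstream POE test.

The per-individual design codes are

    A : minor-allele count (0, 1, 2)            additive
    D : heterozygosity indicator (0, 1)          dominance
    P : parent-of-origin code, +1 if the minor allele is maternal,
        -1 if paternal, 0 for homozygotes        parent-of-origin

so the four ordered genotypes (paternal allele first) map to design rows

    major/major -> [1, 0, 0,  0]
    major/minor -> [1, 1, 1, +1]   (minor allele maternal)
    minor/major -> [1, 1, 1, -1]   (minor allele paternal)
    minor/minor -> [1, 2, 0,  0]

Under Hardy-Weinberg equilibrium with random mating the two heterozygote
orderings are equally frequent, which makes the P column orthogonal to the
centered A and D columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeDuoSet",
    "TransmissionCodes",
    "resolve_duo_transmission",
    "resolve_duo_transmission_matrix",
    "codes_from_phased",
    "build_codes",
    "encode_design",
]

#: sentinel for missing / unresolvable genotype or transmission codes
MISSING = np.int8(-9)


@dataclass
class GenotypeDuoSet:
    """Child and mother minor-allele-count genotypes plus SNP metadata.

    ``child`` and ``mother`` are ``(n_duos, n_snps)`` int8 arrays of
    minor-allele counts with :data:`MISSING` for missing calls.  ``snp_meta``
    has one row per SNP with columns ``id, chrom, pos, ref, alt, minor_allele,
    maf`` (1-based positions).  ``child_phase`` optionally stores the child's
    ordered alleles as an ``(n_duos, n_snps, 2)`` array of minor-allele
    indicators with axis 2 ordered (paternal, maternal).
    """

    samples: list[str]
    child: np.ndarray
    mother: np.ndarray
    snp_meta: pd.DataFrame
    child_phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.child = np.asarray(self.child, dtype=np.int8)
        self.mother = np.asarray(self.mother, dtype=np.int8)
        if self.child.shape != self.mother.shape:
            raise ValueError("child and mother genotype matrices must have the same shape")
        if self.child.shape != (len(self.samples), len(self.snp_meta)):
            raise ValueError("genotype matrix shape does not match samples x snp_meta")

    @property
    def n_duos(self) -> int:
        return self.child.shape[0]

    @property
    def n_snps(self) -> int:
        return self.child.shape[1]

    def recompute_maf(self) -> np.ndarray:
        """Minor-allele frequency recomputed from the child genotypes."""
        gt = np.ma.masked_equal(self.child, MISSING)
        return np.asarray(gt.mean(axis=0) / 2.0)


@dataclass
class TransmissionCodes:
    """Per child x SNP additive / dominance / parent-of-origin codes.

    ``A`` holds minor-allele counts, ``D`` the heterozygosity indicator and
    ``P`` the parent-of-origin code; all are float arrays with ``nan`` for
    missing (unresolvable) entries.  Invariants: ``P != 0`` iff ``A == 1``
    iff ``D == 1`` wherever defined.
    """

    samples: list[str]
    snp_ids: list[str]
    A: np.ndarray
    D: np.ndarray
    P: np.ndarray
    #: per-entry flag for Mendelian-inconsistent duo genotypes
    mendel_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mendel_flags is None:
            self.mendel_flags = np.zeros(self.A.shape, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (sample, snp, A, D, P) table."""
        n, m = self.A.shape
        return pd.DataFrame(
            {
                "sample": np.repeat(self.samples, m),
                "snp": np.tile(self.snp_ids, n),
                "A": self.A.ravel(),
                "D": self.D.ravel(),
                "P": self.P.ravel(),
            }
        )


def resolve_duo_transmission(child_gt: int, mother_gt: int) -> int:
    """Resolve the POE code for one child at one SNP from duo genotypes.

    Parameters are minor-allele counts in {0, 1, 2} (or :data:`MISSING`).
    Returns +1 (minor allele maternal), -1 (paternal), 0 (homozygous child)
    or :data:`MISSING` (unresolvable or Mendelian-inconsistent).

    Mendelian inconsistencies (child homozygous for an allele the mother
    cannot have transmitted) are returned as :data:`MISSING`; use
    :func:`resolve_duo_transmission_matrix` to obtain the inconsistency flags.
    """
    p, flag = _resolve_single(child_gt, mother_gt)
    return p


def _resolve_single(child_gt: int, mother_gt: int) -> tuple[int, bool]:
    if child_gt == MISSING or mother_gt == MISSING:
        return int(MISSING), False
    if child_gt == 0:
        return (int(MISSING), True) if mother_gt == 2 else (0, False)
    if child_gt == 2:
        return (int(MISSING), True) if mother_gt == 0 else (0, False)
    # child heterozygous: any mother genotype is Mendelian-compatible
    if mother_gt == 2:
        return 1, False  # mother can only transmit the minor allele
    if mother_gt == 0:
        return -1, False  # minor allele must be paternal
    return int(MISSING), False  # double heterozygote: ambiguous


def resolve_duo_transmission_matrix(
    child: np.ndarray, mother: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised duo resolution.

    Returns ``(P, mendel_flags)`` where ``P`` is a float array with values in
    {-1, 0, +1, nan} and ``mendel_flags`` marks Mendelian-inconsistent
    entries (which are also nan in ``P``).
    """
    child = np.asarray(child)
    mother = np.asarray(mother)
    P = np.full(child.shape, np.nan)
    missing = (child == MISSING) | (mother == MISSING)
    mendel = (~missing) & (((child == 0) & (mother == 2)) | ((child == 2) & (mother == 0)))
    hom = (~missing) & (~mendel) & (child != 1)
    P[hom] = 0.0
    het = (~missing) & (child == 1)
    P[het & (mother == 2)] = 1.0
    P[het & (mother == 0)] = -1.0
    # het child with het mother stays nan
    return P, mendel


def codes_from_phased(paternal_minor: np.ndarray, maternal_minor: np.ndarray) -> TransmissionCodes:
    """Build codes from phased child genotypes (paternal|maternal order).

    Arguments are ``(n, m)`` arrays of minor-allele indicators (0/1, with
    :data:`MISSING` allowed) for the paternal and maternal allele of each
    child.  Sample/SNP labels are filled with positional defaults; callers
    holding a :class:`GenotypeDuoSet` should use :func:`build_codes`.
    """
    pat = np.asarray(paternal_minor)
    mat = np.asarray(maternal_minor)
    if pat.shape != mat.shape:
        raise ValueError("paternal and maternal allele arrays must have the same shape")
    missing = (pat == MISSING) | (mat == MISSING)
    A = (pat + mat).astype(float)
    D = (A == 1).astype(float)
    P = np.where(A == 1, mat.astype(float) - pat.astype(float), 0.0)
    for arr in (A, D, P):
        arr[missing] = np.nan
    n, m = pat.shape
    return TransmissionCodes(
        samples=[f"S{i}" for i in range(n)],
        snp_ids=[f"snp{j}" for j in range(m)],
        A=A,
        D=D,
        P=P,
    )


def build_codes(duos: GenotypeDuoSet, use_phase: bool = True) -> TransmissionCodes:
    """Additive/dominance/POE codes for a duo set.

    If the child genotypes carry phase information (``child_phase``) and
    ``use_phase`` is true, the POE code is read directly from the declared
    paternal|maternal allele order; otherwise it is resolved by Mendelian
    duo logic (double heterozygotes missing).
    """
    A = np.where(duos.child == MISSING, np.nan, duos.child).astype(float)
    D = np.where(np.isnan(A), np.nan, (A == 1).astype(float))
    if use_phase and duos.child_phase is not None:
        codes = codes_from_phased(duos.child_phase[:, :, 0], duos.child_phase[:, :, 1])
        P, mendel = codes.P, np.zeros(A.shape, dtype=bool)
    else:
        P, mendel = resolve_duo_transmission_matrix(duos.child, duos.mother)
    P = np.where(np.isnan(A), np.nan, P)
    return TransmissionCodes(
        samples=list(duos.samples),
        snp_ids=list(duos.snp_meta["id"]),
        A=A,
        D=D,
        P=P,
        mendel_flags=mendel,
    )


_DESIGN_ROWS = {
    (0, 0): np.array([1.0, 0.0, 0.0, 0.0]),  # major homozygote  (AA)
    (1, 1): np.array([1.0, 1.0, 1.0, 1.0]),  # het, minor maternal (Aa)
    (1, -1): np.array([1.0, 1.0, 1.0, -1.0]),  # het, minor paternal (aA)
    (2, 0): np.array([1.0, 2.0, 0.0, 0.0]),  # minor homozygote  (aa)
}


def encode_design(A: float, P: float) -> np.ndarray:
    """Design row ``[1, A, D, P]`` for one individual.

    Raises ``ValueError`` for missing P (such rows are excluded from fitting)
    or inconsistent (A, P) combinations.
    """
    if np.isnan(A) or np.isnan(P):
        raise ValueError("missing genotype or POE code: row excluded from fitting")
    key = (int(A), int(P))
    if key not in _DESIGN_ROWS:
        raise ValueError(f"inconsistent (A, P) combination: {key}")
    return _DESIGN_ROWS[key].copy()


def design_matrix(codes: TransmissionCodes, snp_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Full-cohort design ``[1, A, D, P]`` for one SNP and its row mask.

    Returns ``(X, keep)`` where ``keep`` marks rows with fully observed
    codes; ``X`` has one row per kept individual.
    """
    A = codes.A[:, snp_index]
    D = codes.D[:, snp_index]
    P = codes.P[:, snp_index]
    keep = ~(np.isnan(A) | np.isnan(P))
    X = np.column_stack([np.ones(keep.sum()), A[keep], D[keep], P[keep]])
    return X, keep
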
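"""Allele-level stochastic machinery of CRISPR suppression gene drives.

This module implements the germline processes that bias inheritance in the
simulated drives:

* **Homing** — in a drive heterozygote, Cas cuts intact gRNA recognition
  sites on the wild-type homologue; homology-directed repair (HDR) converts
  it to a drive allele, while non-homologous end joining (NHEJ) produces
  resistance alleles (in-frame repairs keep the fertility gene functional,
  frameshifts and lost intervening blocks destroy it).
* **Cleave-and-rescue** — Cas cuts a haploinsufficient essential gene whose
  recoded, uncleavable rescue copy rides on the drive cassette; offspring
  need exactly two functional copies (target or rescue) to develop.
* **Daisyfield gating** — gRNAs sit on unlinked "daisy" elements inherited
  Mendelianly, so germline Cas activity requires at least one daisy element
  ("no daisy, no drive") and the drive self-limits as the field dilutes.
* **Driving-Y** — a Y-linked drive that skews offspring toward males.

Two parallel implementations are provided: a scalar, readable one operating
on single :class:`Genotype` values (`make_gametes` and friends) and a
vectorised batch form (`transmit_homing_batch`, `transmit_clvr_batch`) used
by the population engine.  The two are cross-checked distributionally in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from math import comb
from typing import Tuple

import numpy as np

__all__ = [
    "Architecture",
    "ViabilityMode",
    "ClvrTargetMode",
    "DriveParams",
    "HomingAllele",
    "ClvrTargetAllele",
    "Genotype",
    "cleave_rescue_transition_prob",
    "cleavage_probability_rows",
    "drive_active",
    "germline_clvr_cleavage",
    "germline_homing",
    "daisy_inheritance",
    "offspring_sex",
    "offspring_viability",
    "female_is_fertile",
    "make_gametes",
    "transmit_homing_batch",
    "transmit_clvr_batch",
]

WILD = 0
DRIVE = 1


class Architecture(str, Enum):
    """Drive cassette layouts understood by the simulator."""

    WILDTYPE = "wildtype"
    HOMING = "homing"
    CLVR = "clvr"
    HOMING_CLVR = "homing_clvr"
    HDCLVR = "hdclvr"
    DRIVING_Y = "driving_y"
    DRIVING_Y_CLVR = "driving_y_clvr"

    @property
    def has_homing(self) -> bool:
        return self in _HOMING_ARCHS

    @property
    def has_clvr(self) -> bool:
        return self in _CLVR_ARCHS

    @property
    def has_daisyfield(self) -> bool:
        return self is Architecture.HDCLVR

    @property
    def has_driving_y(self) -> bool:
        return self in _DRIVING_Y_ARCHS

    @property
    def has_homing_locus_cassette(self) -> bool:
        """Whether a drive cassette disrupts the female-fertility gene."""
        return self in (_HOMING_ARCHS | {Architecture.CLVR})


_HOMING_ARCHS = {Architecture.HOMING, Architecture.HOMING_CLVR, Architecture.HDCLVR}
_CLVR_ARCHS = {
    Architecture.CLVR,
    Architecture.HOMING_CLVR,
    Architecture.HDCLVR,
    Architecture.DRIVING_Y_CLVR,
}
_DRIVING_Y_ARCHS = {Architecture.DRIVING_Y, Architecture.DRIVING_Y_CLVR}


class ViabilityMode(str, Enum):
    EXACT_TWO_COPIES = "exact_two_copies"
    AT_LEAST_TWO_COPIES = "at_least_two_copies"


class ClvrTargetMode(str, Enum):
    EMBRYONIC_LETHAL = "embryonic_lethal"
    BOTH_SEX_FERTILITY = "both_sex_fertility"


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")


@dataclass(frozen=True)
class DriveParams:
    """Molecular parameters of the simulated drive construct.

    Parameters
    ----------
    architecture
        Which drive components are present.
    n_grnas_homing, n_grnas_clvr
        Number of multiplexed gRNA target sites at the homing locus and in
        the cleave-and-rescue target gene.
    P_c
        Probability that Cas cuts an individual intact gRNA site.
    P_n
        Probability a cut homing locus is repaired by NHEJ instead of HDR.
    P_f
        Per-site probability that NHEJ repair destroys gene function
        (a frameshift); an in-frame repair has probability ``1 - P_f``.
    P_b
        Probability that the DNA block between two simultaneous cuts is
        retained rather than excised.
    driving_y_skew
        Probability that an offspring of a driving-Y father is male.
    daisyfield_size
        Number of daisy elements carried by engineered (released) animals.
    """

    architecture: Architecture = Architecture.HDCLVR
    n_grnas_homing: int = 1
    n_grnas_clvr: int = 4
    P_c: float = 0.95
    P_n: float = 0.02
    P_f: float = 0.667
    P_b: float = 0.2
    driving_y_skew: float = 0.95
    daisyfield_size: int = 30
    viability_mode: ViabilityMode = ViabilityMode.EXACT_TWO_COPIES
    clvr_target_mode: ClvrTargetMode = ClvrTargetMode.EMBRYONIC_LETHAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "architecture", Architecture(self.architecture))
        object.__setattr__(self, "viability_mode", ViabilityMode(self.viability_mode))
        object.__setattr__(
            self, "clvr_target_mode", ClvrTargetMode(self.clvr_target_mode)
        )
        for name in ("P_c", "P_n", "P_f", "P_b", "driving_y_skew"):
            _check_prob(name, getattr(self, name))
        for name in ("n_grnas_homing", "n_grnas_clvr", "daisyfield_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.architecture.has_clvr and self.n_grnas_clvr < 1:
            raise ValueError(
                "n_grnas_clvr must be >= 1 for architectures with a "
                "cleave-and-rescue component"
            )
        if self.architecture.has_homing and self.n_grnas_homing < 1:
            raise ValueError(
                "n_grnas_homing must be >= 1 for architectures with a homing component"
            )
        if self.architecture.has_daisyfield and self.daisyfield_size < 1:
            raise ValueError("daisyfield architectures need daisyfield_size >= 1")


@dataclass(frozen=True)
class HomingAllele:
    """One allele of the haplosufficient female-fertility gene.

    ``site_intact`` tracks, per multiplexed gRNA, whether the recognition
    site is still cleavable.  A drive allele is never self-cleaved and the
    inserted cassette destroys gene function.
    """

    kind: str  # "wild" or "drive"
    site_intact: Tuple[bool, ...]
    gene_functional: bool

    def __post_init__(self) -> None:
        if self.kind not in ("wild", "drive"):
            raise ValueError(f"unknown allele kind {self.kind!r}")
        if self.kind == "drive" and (self.gene_functional or any(self.site_intact)):
            raise ValueError("a drive allele is non-functional and uncleavable")

    @property
    def is_drive(self) -> bool:
        return self.kind == "drive"

    @property
    def n_intact(self) -> int:
        return sum(self.site_intact)

    @property
    def is_resistant(self) -> bool:
        """Sequence-changed non-drive allele (any site no longer cleavable)."""
        return self.kind == "wild" and (
            not all(self.site_intact) or not self.gene_functional
        )

    @classmethod
    def wild(cls, n_sites: int) -> "HomingAllele":
        return cls("wild", (True,) * n_sites, True)

    @classmethod
    def drive(cls, n_sites: int) -> "HomingAllele":
        return cls("drive", (False,) * n_sites, False)


@dataclass(frozen=True)
class ClvrTargetAllele:
    """One allele of the haploinsufficient cleave-and-rescue target gene.

    The recoded rescue copy is represented implicitly: every drive allele at
    the homing locus contributes one uncleavable functional copy.
    """

    n_intact_sites: int
    gene_functional: bool

    def __post_init__(self) -> None:
        if self.n_intact_sites < 0:
            raise ValueError("n_intact_sites must be >= 0")

    @classmethod
    def wild(cls, n_sites: int) -> "ClvrTargetAllele":
        return cls(n_sites, True)

    @classmethod
    def broken(cls) -> "ClvrTargetAllele":
        return cls(0, False)


@dataclass(frozen=True)
class Genotype:
    """Full drive-relevant genotype of one individual."""

    homing: Tuple[HomingAllele, HomingAllele]
    clvr: Tuple[ClvrTargetAllele, ClvrTargetAllele]
    daisies: int = 0
    driving_y: bool = False
    sex: str = "female"

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.driving_y and self.sex != "male":
            raise ValueError("a driving-Y carrier must be male")
        if self.daisies < 0:
            raise ValueError("daisies must be >= 0")

    @property
    def n_drive_alleles(self) -> int:
        return sum(a.is_drive for a in self.homing)

    @classmethod
    def wildtype(cls, params: DriveParams, sex: str = "female") -> "Genotype":
        return cls(
            homing=(
                HomingAllele.wild(params.n_grnas_homing),
                HomingAllele.wild(params.n_grnas_homing),
            ),
            clvr=(
                ClvrTargetAllele.wild(params.n_grnas_clvr),
                ClvrTargetAllele.wild(params.n_grnas_clvr),
            ),
            daisies=0,
            driving_y=False,
            sex=sex,
        )

    @classmethod
    def drive_founder(cls, params: DriveParams, sex: str = "female") -> "Genotype":
        """Engineered release animal.

        Drive heterozygote with one pre-inactivated cleave-and-rescue target
        allele (so the rescue + one functional target give exactly two
        copies), a full daisyfield, and — for driving-Y architectures — a
        male carrying the Y drive.
        """
        arch = params.architecture
        if arch.has_driving_y:
            homing = (
                HomingAllele.wild(params.n_grnas_homing),
                HomingAllele.wild(params.n_grnas_homing),
            )
            driving_y = True
            sex = "male"
        else:
            homing = (
                HomingAllele.drive(params.n_grnas_homing),
                HomingAllele.wild(params.n_grnas_homing),
            )
            driving_y = False
        if arch.has_clvr:
            clvr = (ClvrTargetAllele.broken(), ClvrTargetAllele.wild(params.n_grnas_clvr))
        else:
            clvr = (
                ClvrTargetAllele.wild(params.n_grnas_clvr),
                ClvrTargetAllele.wild(params.n_grnas_clvr),
            )
        daisies = params.daisyfield_size if arch.has_daisyfield else 0
        return cls(homing=homing, clvr=clvr, daisies=daisies, driving_y=driving_y, sex=sex)


# ---------------------------------------------------------------------------
# Cleave-and-rescue cleavage distribution
# ---------------------------------------------------------------------------


def cleave_rescue_transition_prob(i: int, j: int, params: DriveParams) -> float:
    """Probability that a target gene goes from *i* to *j* intact sites
    while remaining functional.

    P_ij = C(i, i-j) * (P_c (1-P_f))^(i-j) * (1-P_c)^j * P_b^max(i-j-1, 0).

    Each of the ``i-j`` cut sites must be cut (P_c) and repaired in frame
    (1-P_f); the ``j`` surviving sites must escape cutting; and every block
    of DNA between two simultaneous cuts must be retained (P_b; no block
    factor when fewer than two cuts).  The residual mass ``1 - sum_j P_ij``
    is the probability the gene is rendered non-functional.
    """
    if i < 0 or j < 0 or j > i or i > params.n_grnas_clvr:
        raise ValueError(f"require 0 <= j <= i <= n_grnas_clvr, got i={i}, j={j}")
    k = i - j
    return (
        comb(i, k)
        * (params.P_c * (1.0 - params.P_f)) ** k
        * (1.0 - params.P_c) ** j
        * params.P_b ** max(k - 1, 0)
    )


@lru_cache(maxsize=64)
def _cleavage_rows(n_sites: int, P_c: float, P_f: float, P_b: float):
    rows = []
    for i in range(n_sites + 1):
        p = np.array(
            [
                comb(i, i - j)
                * (P_c * (1.0 - P_f)) ** (i - j)
                * (1.0 - P_c) ** j
                * P_b ** max(i - j - 1, 0)
                for j in range(i + 1)
            ]
        )
        rows.append(p)
    return tuple(rows)


def cleavage_probability_rows(params: DriveParams):
    """Per-``i`` vectors ``[P_i0, ..., P_ii]``; residual mass is implicit."""
    return _cleavage_rows(params.n_grnas_clvr, params.P_c, params.P_f, params.P_b)


def drive_active(genotype: Genotype, params: DriveParams) -> bool:
    """Whether germline Cas-gRNA activity occurs in this parent.

    Requires a Cas carrier (a drive allele, or the driving Y) and, in
    daisyfield architectures, at least one daisy element supplying gRNAs.
    """
    arch = params.architecture
    if arch is Architecture.WILDTYPE:
        return False
    carrier = genotype.driving_y if arch.has_driving_y else genotype.n_drive_alleles > 0
    if not carrier:
        return False
    if arch.has_daisyfield and genotype.daisies < 1:
        return False
    return True


def germline_clvr_cleavage(
    allele: ClvrTargetAllele, active: bool, params: DriveParams, rng: np.random.Generator
) -> ClvrTargetAllele:
    """Cleave one target allele in an active germline.

    Samples the new intact-site count ``j`` from ``{P_ij}``; the residual
    probability mass destroys gene function (absorbing).
    """
    if not active or not allele.gene_functional:
        return allele
    cum = np.cumsum(cleavage_probability_rows(params)[allele.n_intact_sites])
    j = int(np.searchsorted(cum, rng.random(), side="right"))
    if j > allele.n_intact_sites:
        return ClvrTargetAllele(0, False)
    return ClvrTargetAllele(j, True)


def germline_homing(
    genotype: Genotype, params: DriveParams, rng: np.random.Generator
) -> Tuple[HomingAllele, HomingAllele]:
    """Apply germline homing to a parent's homing-locus alleles.

    In an active drive heterozygote each intact site on the non-drive
    allele is cut independently with probability P_c.  Given at least one
    cut, HDR converts the allele to a drive copy with probability 1-P_n;
    otherwise NHEJ leaves a resistance allele that stays functional only
    if every repair is in frame (1-P_f each) and every intervening block
    is retained (P_b each).
    """
    a, b = genotype.homing
    if not params.architecture.has_homing or not drive_active(genotype, params):
        return (a, b)
    if genotype.n_drive_alleles != 1:
        return (a, b)
    target = b if a.is_drive else a
    cut = [intact and (rng.random() < params.P_c) for intact in target.site_intact]
    k = sum(cut)
    if k == 0:
        converted = target
    elif rng.random() < 1.0 - params.P_n:
        converted = HomingAllele.drive(params.n_grnas_homing)
    else:
        new_sites = tuple(s and not c for s, c in zip(target.site_intact, cut))
        p_keep = (1.0 - params.P_f) ** k * params.P_b ** max(k - 1, 0)
        functional = target.gene_functional and (rng.random() < p_keep)
        converted = HomingAllele("wild", new_sites, functional)
    return (a, converted) if a.is_drive else (converted, b)


def daisy_inheritance(n_mother: int, n_father: int, rng: np.random.Generator) -> int:
    """Each parental daisy element is transmitted independently w.p. 0.5."""
    if n_mother < 0 or n_father < 0:
        raise ValueError("daisy counts must be >= 0")
    return int(rng.binomial(n_mother, 0.5) + rng.binomial(n_father, 0.5))


def offspring_sex(father: Genotype, params: DriveParams, rng: np.random.Generator) -> str:
    """Male w.p. ``driving_y_skew`` for driving-Y fathers, else 0.5."""
    skewed = params.architecture.has_driving_y and father.driving_y
    p_male = params.driving_y_skew if skewed else 0.5
    return "male" if rng.random() < p_male else "female"


def offspring_viability(genotype: Genotype, params: DriveParams) -> bool:
    """Two functional copies of the essential target gene are required.

    Copies = functional target alleles + rescue copies (one per drive
    allele; in the driving-Y cleave-and-rescue variant the Y carries the
    rescue).  ``at_least_two_copies`` models a target whose overexpression
    is tolerated.
    """
    if not params.architecture.has_clvr:
        return True
    copies = sum(a.gene_functional for a in genotype.clvr) + genotype.n_drive_alleles
    if params.architecture is Architecture.DRIVING_Y_CLVR and genotype.driving_y:
        copies += 1
    if params.viability_mode is ViabilityMode.AT_LEAST_TWO_COPIES:
        return copies >= 2
    return copies == 2


def female_is_fertile(genotype: Genotype) -> bool:
    """Haplosufficiency: one functional fertility-gene copy suffices."""
    return any(a.gene_functional for a in genotype.homing)


def make_gametes(
    mother: Genotype, father: Genotype, params: DriveParams, rng: np.random.Generator
) -> Genotype:
    """Produce one offspring genotype from a mating.

    Germline homing and cleave-and-rescue cleavage act independently in
    each parent (no embryonic Cas activity), then one allele per locus per
    parent is drawn uniformly.  Viability filtering is the caller's job.
    """
    m_homing = germline_homing(mother, params, rng)
    m_active = drive_active(mother, params) and params.architecture.has_clvr
    m_clvr = tuple(germline_clvr_cleavage(a, m_active, params, rng) for a in mother.clvr)
    f_homing = germline_homing(father, params, rng)
    f_active = drive_active(father, params) and params.architecture.has_clvr
    f_clvr = tuple(germline_clvr_cleavage(a, f_active, params, rng) for a in father.clvr)

    homing = (m_homing[rng.integers(2)], f_homing[rng.integers(2)])
    clvr = (m_clvr[rng.integers(2)], f_clvr[rng.integers(2)])
    daisies = daisy_inheritance(mother.daisies, father.daisies, rng)
    sex = offspring_sex(father, params, rng)
    driving_y = (
        sex == "male" and father.driving_y and params.architecture.has_driving_y
    )
    return Genotype(homing=homing, clvr=clvr, daisies=daisies, driving_y=driving_y, sex=sex)


# ---------------------------------------------------------------------------
# Vectorised batch transmission (used by the population engine)
# ---------------------------------------------------------------------------


def transmit_homing_batch(
    kind2: np.ndarray,
    intact2: np.ndarray,
    func2: np.ndarray,
    active: np.ndarray,
    params: DriveParams,
    rng: np.random.Generator,
):
    """Sample one homing-locus gamete per row of gathered parental alleles.

    ``kind2``/``intact2``/``func2`` have shape (M, 2): the two alleles of
    the transmitting parent for each of M conceptions. ``active`` flags
    germline Cas activity per row.  Returns ``(kind, intact, functional)``
    gamete arrays of shape (M,).

    Site exchangeability lets the boolean site vector be summarised by its
    intact count: cuts are Binomial(n_intact, P_c) and all cut sites lose
    their recognition sequence under NHEJ.
    """
    M = kind2.shape[0]
    kind2 = kind2.copy()
    intact2 = intact2.copy()
    func2 = func2.copy()
    if params.architecture.has_homing and M:
        het = (kind2 == DRIVE).sum(axis=1) == 1
        rows = np.flatnonzero(active & het)
        if rows.size:
            wcol = (kind2[rows, 0] == DRIVE).astype(np.intp)  # index of wild allele
            cuts = rng.binomial(intact2[rows, wcol], params.P_c)
            any_cut = cuts > 0
            conv = any_cut & (rng.random(rows.size) < 1.0 - params.P_n)
            r, c = rows[conv], wcol[conv]
            kind2[r, c] = DRIVE
            intact2[r, c] = 0
            func2[r, c] = False
            nhej = any_cut & ~conv
            r, c, k = rows[nhej], wcol[nhej], cuts[nhej]
            intact2[r, c] -= k
            p_keep = (1.0 - params.P_f) ** k * params.P_b ** np.maximum(k - 1, 0)
            func2[r, c] &= rng.random(r.size) < p_keep
    pick = rng.integers(0, 2, M)
    ar = np.arange(M)
    return kind2[ar, pick], intact2[ar, pick], func2[ar, pick]


def transmit_clvr_batch(
    intact2: np.ndarray,
    func2: np.ndarray,
    active: np.ndarray,
    params: DriveParams,
    rng: np.random.Generator,
):
    """Sample one cleave-and-rescue target gamete per row.

    Both parental target alleles are cleaved in active germlines (rescue
    copies are implicit and never cleaved), then one is drawn uniformly.
    """
    M = intact2.shape[0]
    intact2 = intact2.copy()
    func2 = func2.copy()
    if params.architecture.has_clvr and M:
        rows_by_i = cleavage_probability_rows(params)
        cum_by_i = [np.cumsum(p) for p in rows_by_i]
        for col in (0, 1):
            sel = np.flatnonzero(active & func2[:, col])
            if not sel.size:
                continue
            ivals = intact2[sel, col]
            u = rng.random(sel.size)
            new_i = np.zeros(sel.size, dtype=intact2.dtype)
            new_f = np.zeros(sel.size, dtype=bool)
            for i in np.unique(ivals):
                m = ivals == i
                j = np.searchsorted(cum_by_i[i], u[m], side="right")
                dead = j > i
                new_i[m] = np.where(dead, 0, j)
                new_f[m] = ~dead
            intact2[sel, col] = new_i
            func2[sel, col] = new_f
    pick = rng.integers(0, 2, M)
    ar = np.arange(M)
    return intact2[ar, pick], func2[ar, pick]
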
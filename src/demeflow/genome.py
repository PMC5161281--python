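"""Binary ancestry-marker genomes and their transmission.

Each individual carries ancestry-informative markers from two source
populations, encoded as binary alleles (Papuan = 0, Asian = 1):

* 25 diploid autosomal markers, completely unlinked;
* 25 X-chromosome markers, partially linked (two copies in females, one
  in males), recombining in female meiosis with a Poisson number of
  crossovers on a genetic map of configurable length;
* a single fully linked mtDNA marker (maternal) and, in males, a single
  fully linked Y marker (paternal).

There is no mutation: every child allele is a copy of a parental allele,
so ancestry fractions evolve purely through transmission and mating.

Functions accept either :class:`Genome` instances or the raw allele
arrays, so the vectorised simulation engine and the object interface
share a single transmission implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FEMALE",
    "MALE",
    "PAPUAN",
    "ASIAN",
    "N_AUTO_MARKERS",
    "N_X_MARKERS",
    "DEFAULT_X_MAP_LENGTH",
    "Genome",
    "default_x_positions",
    "make_founder_genome",
    "transmit_autosomes",
    "sample_x_breakpoints",
    "transmit_x",
    "transmit_haploids",
    "make_child_genome",
    "ancestry_fraction",
    "classify_ethnicity",
]

FEMALE = 0
MALE = 1

PAPUAN = 0
ASIAN = 1

N_AUTO_MARKERS = 25
N_X_MARKERS = 25

#: X genetic map length per female meiosis, in Morgans (~180 cM in
#: published human female X maps).
DEFAULT_X_MAP_LENGTH = 1.8

SYSTEMS = ("autosome", "x", "mt", "y", "all")


def default_x_positions(n_markers: int = N_X_MARKERS) -> np.ndarray:
    """Marker positions on the unit genetic map, uniformly spaced.

    Marker ``k`` sits at ``(k + 0.5) / n``, i.e. at bin midpoints of an
    even partition of [0, 1).
    """
    return (np.arange(n_markers) + 0.5) / n_markers


_DEFAULT_X_POSITIONS = default_x_positions()


@dataclass
class Genome:
    """Marker state of one individual.

    ``autosomes`` is (25, 2); ``x`` is (25, 2) for females and (25, 1)
    for males; ``mt`` is a single bit; ``y`` is a single bit for males
    and ``None`` for females.
    """

    sex: int
    autosomes: np.ndarray
    x: np.ndarray
    mt: int
    y: int | None = None

    def __post_init__(self) -> None:
        self.autosomes = np.asarray(self.autosomes, dtype=np.uint8)
        self.x = np.asarray(self.x, dtype=np.uint8)
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.autosomes.shape != (N_AUTO_MARKERS, 2):
            raise ValueError("autosome array must be 25x2")
        ploidy = 2 if self.sex == FEMALE else 1
        if self.x.shape != (N_X_MARKERS, ploidy):
            raise ValueError(
                f"x array must be {N_X_MARKERS}x{ploidy} for this sex"
            )
        if (self.sex == MALE) != (self.y is not None):
            raise ValueError("y allele present iff male")
        for arr in (self.autosomes, self.x):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError("alleles must be binary")
        if self.mt not in (0, 1):
            raise ValueError("mt allele must be binary")
        if self.y is not None and self.y not in (0, 1):
            raise ValueError("y allele must be binary")

    @property
    def x_ploidy(self) -> int:
        return self.x.shape[1]


def make_founder_genome(ethnicity: int, sex: int, rng=None) -> Genome:
    """Genome of an unadmixed founder: every allele equals ``ethnicity``."""
    if ethnicity not in (PAPUAN, ASIAN):
        raise ValueError(f"invalid ethnicity {ethnicity!r}")
    if sex not in (FEMALE, MALE):
        raise ValueError(f"invalid sex {sex!r}")
    bit = np.uint8(ethnicity)
    ploidy = 2 if sex == FEMALE else 1
    return Genome(
        sex=sex,
        autosomes=np.full((N_AUTO_MARKERS, 2), bit),
        x=np.full((N_X_MARKERS, ploidy), bit),
        mt=int(bit),
        y=int(bit) if sex == MALE else None,
    )


def _autosomes_of(parent) -> np.ndarray:
    return parent.autosomes if isinstance(parent, Genome) else np.asarray(parent)


def _x_of(parent) -> np.ndarray:
    arr = parent.x if isinstance(parent, Genome) else np.asarray(parent)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def transmit_autosomes(mother, father, rng) -> np.ndarray:
    """One Mendelian draw of 25 unlinked diploid markers.

    For each marker, one allele is picked uniformly from the mother's two
    and one from the father's two, independently across markers. Returns
    a (25, 2) array with maternal alleles in column 0.
    """
    ma = _autosomes_of(mother)
    fa = _autosomes_of(father)
    n = ma.shape[0]
    rows = np.arange(n)
    mat = ma[rows, rng.integers(0, 2, n)]
    pat = fa[rows, rng.integers(0, 2, n)]
    return np.stack([mat, pat], axis=1)


def sample_x_breakpoints(map_length_morgans: float, rng) -> np.ndarray:
    """Crossover positions of one female X meiosis on the unit map.

    The number of breakpoints is Poisson(map length in Morgans); the
    positions are i.i.d. uniform on [0, 1), returned sorted.
    """
    if not map_length_morgans > 0:
        raise ValueError("map length must be positive")
    k = rng.poisson(map_length_morgans)
    return np.sort(rng.random(k))


def transmit_x(
    mother,
    father,
    child_sex: int,
    rng,
    map_length: float = DEFAULT_X_MAP_LENGTH,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """X alleles of a child.

    The maternal gamete starts on one of the mother's two copies (fair
    coin) and switches copy at each recombination breakpoint; every
    marker takes the allele of the copy active at its map position.
    Daughters additionally receive the father's single X intact; sons
    carry only the maternal gamete (no recombination occurs in the
    father, who has a single copy).
    """
    if child_sex not in (FEMALE, MALE):
        raise ValueError(f"invalid child sex {child_sex!r}")
    mx = _x_of(mother)
    if positions is None:
        positions = (
            _DEFAULT_X_POSITIONS
            if mx.shape[0] == N_X_MARKERS
            else default_x_positions(mx.shape[0])
        )
    breakpoints = sample_x_breakpoints(map_length, rng)
    start = int(rng.integers(0, 2))
    copy_idx = (start + np.searchsorted(breakpoints, positions, side="right")) % 2
    gamete = mx[np.arange(mx.shape[0]), copy_idx]
    if child_sex == MALE:
        return gamete[:, None].astype(np.uint8)
    fx = _x_of(father)
    return np.stack([gamete, fx[:, 0]], axis=1).astype(np.uint8)


def transmit_haploids(mother, father, child_sex: int) -> tuple[int, int | None]:
    """(mtDNA, Y) of a child: mt from the mother; Y from the father iff male."""
    mt = int(mother.mt if isinstance(mother, Genome) else mother)
    if child_sex == MALE:
        y = int(father.y if isinstance(father, Genome) else father)
        return mt, y
    return mt, None


def make_child_genome(
    mother: Genome,
    father: Genome,
    sex: int,
    rng,
    map_length: float = DEFAULT_X_MAP_LENGTH,
) -> Genome:
    """Full genome of one child from two parents of opposite sex."""
    if mother.sex != FEMALE or father.sex != MALE:
        raise ValueError("mother must be female and father male")
    mt, y = transmit_haploids(mother, father, sex)
    return Genome(
        sex=sex,
        autosomes=transmit_autosomes(mother, father, rng),
        x=transmit_x(mother, father, sex, rng, map_length=map_length),
        mt=mt,
        y=y,
    )


def _compartment_counts(genome: Genome, system: str) -> tuple[int, int]:
    if system == "autosome":
        return int(genome.autosomes.sum()), genome.autosomes.size
    if system == "x":
        return int(genome.x.sum()), genome.x.size
    if system == "mt":
        return int(genome.mt), 1
    if system == "y":
        if genome.sex != MALE:
            raise ValueError("y ancestry requested for a female")
        return int(genome.y), 1
    raise ValueError(f"unknown marker system {system!r}")


def ancestry_fraction(genome: Genome, system: str = "all") -> float:
    """Fraction of Asian alleles in the named compartment.

    ``"all"`` pools every allele the individual carries: 50 autosomal,
    25 (males) or 50 (females) X, 1 mtDNA and, in males, 1 Y allele.
    """
    if system == "all":
        systems = ["autosome", "x", "mt"] + (["y"] if genome.sex == MALE else [])
        asian = total = 0
        for s in systems:
            a, t = _compartment_counts(genome, s)
            asian += a
            total += t
        return asian / total
    asian, total = _compartment_counts(genome, system)
    return asian / total


def classify_ethnicity(genome: Genome) -> int:
    """Asian iff at least 50% of all carried alleles are Asian (inclusive)."""
    systems = ["autosome", "x", "mt"] + (["y"] if genome.sex == MALE else [])
    asian = total = 0
    for s in systems:
        a, t = _compartment_counts(genome, s)
        asian += a
        total += t
    return ASIAN if 2 * asian >= total else PAPUAN
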
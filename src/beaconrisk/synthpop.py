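"""Synthetic populations with the statistical structure assumed by the
beacon membership-inference model.

The generator emulates a panel of biallelic SNPs whose alternate-allele
frequencies follow the standard neutral site-frequency spectrum for a
population of ``M`` diploids (derived-allele count ``i`` drawn with
probability proportional to ``1/i`` over ``1..2M-1``, frequency
``f = i/2M``), diploid genotypes drawn as Binomial(2, f) under
Hardy-Weinberg equilibrium, relatives built by per-site copying with a
kinship coefficient, and the noisy copy of a target genome an adversary
would hold after sequencing.

All randomness flows through explicit :class:`numpy.random.Generator`
objects derived from integer seeds; there is no global random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SNPPanel",
    "GenotypeMatrix",
    "SimulationConfig",
    "sample_neutral_frequencies",
    "sample_genotypes",
    "make_relative",
    "apply_sequencing_error",
    "write_panel_tsv",
    "read_panel_tsv",
    "save_genotypes",
    "load_genotypes",
]


@dataclass(frozen=True)
class SNPPanel:
    """Per-SNP alternate-allele frequencies and coordinates.

    Parameters
    ----------
    freqs
        Alternate-allele frequency per SNP, each strictly in (0, 1).
    chrom
        Chromosome label per SNP.
    pos
        0-based coordinate per SNP, strictly increasing within a chromosome.
    """

    freqs: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        chrom = np.asarray(self.chrom, dtype=object)
        pos = np.asarray(self.pos, dtype=np.int64)
        if not (freqs.ndim == chrom.ndim == pos.ndim == 1):
            raise ValueError("freqs, chrom and pos must be 1-d arrays")
        if not (len(freqs) == len(chrom) == len(pos)):
            raise ValueError("freqs, chrom and pos must have equal length")
        if len(freqs) < 1:
            raise ValueError("a panel needs at least one SNP")
        if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
            raise ValueError("frequencies must be strictly in (0, 1)")
        if np.any(pos < 0):
            raise ValueError("positions must be non-negative")
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"positions must be strictly increasing within chrom {c!r}"
                )
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos", pos)

    @property
    def num_snps(self) -> int:
        return len(self.freqs)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.freqs)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid alternate-allele counts (0/1/2) for individuals x SNPs."""

    entries: np.ndarray
    panel: SNPPanel

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries)
        if entries.ndim != 2:
            raise ValueError("entries must be a 2-d individuals x SNPs matrix")
        if entries.shape[1] != self.panel.num_snps:
            raise ValueError(
                f"matrix has {entries.shape[1]} columns but the panel has "
                f"{self.panel.num_snps} SNPs"
            )
        if entries.size and (entries.min() < 0 or entries.max() > 2):
            raise ValueError("genotype entries must be in {0, 1, 2}")
        object.__setattr__(self, "entries", entries.astype(np.int8, copy=False))

    @property
    def num_individuals(self) -> int:
        return self.entries.shape[0]


_KINSHIP_LEVELS = (1.0, 0.5, 0.25, 0.125)


@dataclass
class SimulationConfig:
    """Study-condition bundle for an end-to-end simulation.

    Defaults are the conditions of the power experiments: a population of
    20,000 diploids, 1,000,000 SNPs (scale ``num_snps`` down for quick
    runs), a beacon of 1,000 members, 400 in-beacon and 400 out-of-beacon
    targets, and a per-query mismatch rate of 1e-3.
    """

    population_size: int = 20_000
    num_snps: int = 1_000_000
    beacon_size: int = 1_000
    cases: int = 400
    controls: int = 400
    delta: float = 1e-3
    kinship: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.num_snps < 1:
            raise ValueError("num_snps must be positive")
        if self.beacon_size < 1:
            raise ValueError("beacon_size must be positive")
        if self.beacon_size + self.controls > self.population_size:
            raise ValueError("beacon_size + controls exceeds population_size")
        if self.cases > self.beacon_size:
            raise ValueError("cases cannot exceed beacon_size")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must lie in [0, 1)")
        if self.kinship is not None and not 0.0 <= self.kinship <= 1.0:
            raise ValueError("kinship must lie in [0, 1]")


def sample_neutral_frequencies(
    num_snps: int, population_size: int, seed: int | None = None
) -> SNPPanel:
    """Sample a SNP panel from the standard neutral site-frequency spectrum.

    Derived-allele counts ``i`` are drawn over ``{1, ..., 2M-1}`` with
    probability proportional to ``1/i`` for ``M = population_size``
    diploids; the alternate-allele frequency is ``i / 2M``. All SNPs are
    placed on a single chromosome at consecutive coordinates.
    """
    if num_snps < 1:
        raise ValueError("num_snps must be positive")
    if population_size < 2:
        raise ValueError("population_size must be at least 2")
    rng = np.random.default_rng(seed)
    two_m = 2 * population_size
    counts = np.arange(1, two_m)
    weights = 1.0 / counts
    weights /= weights.sum()
    drawn = rng.choice(counts, size=num_snps, p=weights)
    freqs = drawn / two_m
    return SNPPanel(
        freqs=freqs,
        chrom=np.repeat(np.array(["1"], dtype=object), num_snps),
        pos=np.arange(num_snps, dtype=np.int64),
    )


def sample_genotypes(
    panel: SNPPanel, num_individuals: int, seed: int | None = None
) -> GenotypeMatrix:
    """Draw independent diploid genotypes, Binomial(2, f) per cell."""
    if num_individuals < 1:
        raise ValueError("num_individuals must be positive")
    rng = np.random.default_rng(seed)
    entries = rng.binomial(
        2, panel.freqs, size=(num_individuals, panel.num_snps)
    ).astype(np.int8)
    return GenotypeMatrix(entries=entries, panel=panel)


def make_relative(
    target_row: np.ndarray,
    panel: SNPPanel,
    kinship: float,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate a relative of a target genome.

    Per SNP, with probability ``kinship`` the target's genotype is copied;
    otherwise a fresh Binomial(2, f) genotype is drawn. ``kinship = 1``
    yields an identical genome (twin); the conventional levels are
    1 (twin), 0.5 (parent-offspring / sibling), 0.25, 0.125.
    """
    if not 0.0 <= kinship <= 1.0:
        raise ValueError("kinship must lie in [0, 1]")
    target_row = np.asarray(target_row)
    if target_row.shape != (panel.num_snps,):
        raise ValueError("target_row length must equal panel.num_snps")
    rng = np.random.default_rng(seed)
    copy_mask = rng.random(panel.num_snps) < kinship
    fresh = rng.binomial(2, panel.freqs).astype(np.int8)
    return np.where(copy_mask, target_row, fresh).astype(np.int8)


def apply_sequencing_error(
    target_row: np.ndarray, delta: float, seed: int | None = None
) -> np.ndarray:
    """Produce the noisy copy of a genome the adversary would hold.

    Each alternate-allele-carrying site is independently reverted to
    homozygous reference with probability ``delta`` (mismatch between the
    adversary's copy and the genome held by the beacon); sites without
    alternate alleles are unchanged.
    """
    if not 0.0 <= delta < 1.0:
        raise ValueError("delta must lie in [0, 1)")
    target_row = np.asarray(target_row)
    out = target_row.copy()
    if delta > 0.0:
        rng = np.random.default_rng(seed)
        alt = np.flatnonzero(target_row > 0)
        revert = alt[rng.random(alt.size) < delta]
        out[revert] = 0
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_panel_tsv(panel: SNPPanel, path: str | Path) -> Path:
    """Write a panel as TSV with columns chrom, pos, f (pos 1-based on disk)."""
    path = Path(path)
    df = pd.DataFrame(
        {"chrom": panel.chrom, "pos": panel.pos + 1, "f": panel.freqs}
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_panel_tsv(path: str | Path) -> SNPPanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    missing = {"chrom", "pos", "f"} - set(df.columns)
    if missing:
        raise ValueError(f"panel TSV is missing columns: {sorted(missing)}")
    return SNPPanel(
        freqs=df["f"].to_numpy(float),
        chrom=df["chrom"].to_numpy(object),
        pos=df["pos"].to_numpy(np.int64) - 1,
    )


def save_genotypes(matrix: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path, Path]:
    """Save a genotype matrix as ``<prefix>.npy`` plus text sidecars.

    The sidecar ``<prefix>.json`` records shape and dtype; the panel is
    written next to it as ``<prefix>.panel.tsv``. The round trip through
    :func:`load_genotypes` is exact.
    """
    prefix = Path(prefix)
    npy = prefix.with_suffix(".npy")
    sidecar = prefix.with_suffix(".json")
    panel_path = Path(str(prefix) + ".panel.tsv")
    np.save(npy, matrix.entries)
    sidecar.write_text(
        json.dumps(
            {
                "individuals": int(matrix.num_individuals),
                "snps": int(matrix.panel.num_snps),
                "dtype": str(matrix.entries.dtype),
                "panel": panel_path.name,
            },
            indent=1,
        )
    )
    write_panel_tsv(matrix.panel, panel_path)
    return npy, sidecar, panel_path


def load_genotypes(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    sidecar = prefix.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    entries = np.load(prefix.with_suffix(".npy"))
    if entries.shape != (meta["individuals"], meta["snps"]):
        raise ValueError("genotype container does not match its sidecar index")
    panel = read_panel_tsv(sidecar.parent / meta["panel"])
    return GenotypeMatrix(entries=entries, panel=panel)
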
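"""The beacon database abstraction.

A beacon answers yes/no to "does any genome in this dataset carry allele A
at position P of chromosome C". Internally coordinates are 0-based; the
on-disk beacon table and VCF use 1-based positions, converted at the
boundary. Simulated panels use the abstract allele token ``ALT``;
nucleotide letters appear only in VCF-derived beacons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synthpop import GenotypeMatrix, SNPPanel

logger = logging.getLogger(__name__)

ALT = "ALT"
_VALID_ALLELES = frozenset({"A", "C", "G", "T", ALT})

__all__ = [
    "ALT",
    "BeaconQuery",
    "BeaconDB",
    "ResponseVector",
    "build_beacon",
    "query_beacon",
    "write_beacon_table",
    "read_beacon_table",
    "import_vcf",
]


@dataclass(frozen=True)
class BeaconQuery:
    """A query triple: chromosome, 0-based position, allele token."""

    chrom: str
    pos: int
    allele: str = ALT

    def __post_init__(self) -> None:
        if self.allele not in _VALID_ALLELES:
            raise ValueError(
                f"allele must be one of {sorted(_VALID_ALLELES)}, got {self.allele!r}"
            )
        if self.pos < 0:
            raise ValueError("pos must be non-negative (0-based)")


@dataclass(frozen=True)
class ResponseVector:
    """The binary sequence of beacon answers x_1..x_n."""

    x: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.int8)
        if x.ndim != 1 or (x.size and not np.isin(x, (0, 1)).all()):
            raise ValueError("responses must be a 1-d 0/1 vector")
        object.__setattr__(self, "x", x)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def sum_x(self) -> int:
        return int(self.x.sum())


@dataclass
class BeaconDB:
    """A beacon: member count plus the catalogued presence bits.

    ``catalog_*`` arrays list every catalogued (chrom, pos, allele) triple;
    ``present`` marks the triples answered "yes". Queries outside the
    catalog answer "no", matching public beacon behaviour.
    """

    n_members: int
    catalog_chrom: np.ndarray
    catalog_pos: np.ndarray
    catalog_allele: np.ndarray
    present: np.ndarray
    provenance: str = "raw"
    mechanism: dict | None = None
    _index: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("a beacon must have at least one member")
        self.catalog_chrom = np.asarray(self.catalog_chrom, dtype=object)
        self.catalog_pos = np.asarray(self.catalog_pos, dtype=np.int64)
        self.catalog_allele = np.asarray(self.catalog_allele, dtype=object)
        self.present = np.asarray(self.present, dtype=bool)
        n = len(self.catalog_pos)
        if not (
            len(self.catalog_chrom) == len(self.catalog_allele) == len(self.present) == n
        ):
            raise ValueError("catalog arrays must have equal length")

    @property
    def N(self) -> int:
        return self.n_members

    @property
    def num_entries(self) -> int:
        return len(self.present)

    def _build_index(self) -> dict:
        if self._index is None:
            self._index = {
                (c, int(p), a): i
                for i, (c, p, a) in enumerate(
                    zip(self.catalog_chrom, self.catalog_pos, self.catalog_allele)
                )
            }
        return self._index

    def contains(self, query: BeaconQuery) -> bool:
        idx = self._build_index().get((query.chrom, query.pos, query.allele))
        return False if idx is None else bool(self.present[idx])

    def present_set(self) -> set[tuple[str, int, str]]:
        return {
            (c, int(p), a)
            for c, p, a in zip(
                self.catalog_chrom[self.present],
                self.catalog_pos[self.present],
                self.catalog_allele[self.present],
            )
        }

    def presence_vector(self, panel: SNPPanel) -> np.ndarray:
        """Presence bit per panel SNP (ALT allele), vectorized.

        Fast path when the catalog was built from the same panel in order;
        otherwise resolved through the triple index.
        """
        if (
            self.num_entries == panel.num_snps
            and np.array_equal(self.catalog_pos, panel.pos)
            and (self.catalog_chrom == panel.chrom).all()
            and (self.catalog_allele == ALT).all()
        ):
            return self.present
        index = self._build_index()
        out = np.zeros(panel.num_snps, dtype=bool)
        for j, (c, p) in enumerate(zip(panel.chrom, panel.pos)):
            i = index.get((c, int(p), ALT))
            if i is not None:
                out[j] = self.present[i]
        return out

    def replace_present(self, present: np.ndarray, provenance: str, mechanism: dict) -> "BeaconDB":
        """Copy of this beacon with new presence bits (same catalog and N)."""
        return BeaconDB(
            n_members=self.n_members,
            catalog_chrom=self.catalog_chrom,
            catalog_pos=self.catalog_pos,
            catalog_allele=self.catalog_allele,
            present=np.asarray(present, dtype=bool),
            provenance=provenance,
            mechanism=mechanism,
        )


def build_beacon(genotypes: GenotypeMatrix, member_indices) -> BeaconDB:
    """Construct a raw beacon from the genotypes of its members.

    A panel SNP is catalogued as present iff at least one member carries
    one or more copies of the alternate allele.
    """
    member_indices = np.asarray(member_indices, dtype=np.int64)
    if member_indices.size == 0:
        raise ValueError("member_indices must be non-empty")
    if member_indices.min() < 0 or member_indices.max() >= genotypes.num_individuals:
        raise ValueError("member_indices out of range for the genotype matrix")
    if len(np.unique(member_indices)) != member_indices.size:
        raise ValueError("member_indices must be unique")
    panel = genotypes.panel
    present = (genotypes.entries[member_indices] > 0).any(axis=0)
    return BeaconDB(
        n_members=int(member_indices.size),
        catalog_chrom=panel.chrom,
        catalog_pos=panel.pos,
        catalog_allele=np.repeat(np.array([ALT], dtype=object), panel.num_snps),
        present=present,
        provenance="raw",
    )


def query_beacon(db: BeaconDB, query: BeaconQuery) -> bool:
    """Answer a single query: yes iff the triple is catalogued present."""
    return db.contains(query)


# ---------------------------------------------------------------------------
# beacon table I/O
# ---------------------------------------------------------------------------

def write_beacon_table(db: BeaconDB, path: str | Path) -> Path:
    """Write the beacon as TSV: header lines ``##N=``/``##provenance=``
    (plus mechanism metadata when perturbed), then one row per catalogued
    triple with columns chrom, pos (1-based on disk), allele, present."""
    path = Path(path)
    lines = [f"##N={db.n_members}", f"##provenance={db.provenance}"]
    if db.mechanism:
        meta = ";".join(f"{k}={v}" for k, v in sorted(db.mechanism.items()))
        lines.append(f"##mechanism={meta}")
    lines.append("#chrom\tpos\tallele\tpresent")
    for c, p, a, pres in zip(
        db.catalog_chrom, db.catalog_pos, db.catalog_allele, db.present
    ):
        lines.append(f"{c}\t{int(p) + 1}\t{a}\t{int(pres)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_beacon_table(path: str | Path) -> BeaconDB:
    path = Path(path)
    n_members = None
    provenance = "raw"
    mechanism = None
    chroms, poss, alleles, present = [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##N="):
                n_members = int(line[4:])
                continue
            if line.startswith("##provenance="):
                provenance = line.split("=", 1)[1]
                continue
            if line.startswith("##mechanism="):
                mechanism = dict(
                    kv.split("=", 1) for kv in line.split("=", 1)[1].split(";")
                )
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            if fields[3] not in ("0", "1"):
                raise ValueError(
                    f"{path}:{lineno}: present column must be 0 or 1, got {fields[3]!r}"
                )
            chroms.append(fields[0])
            poss.append(int(fields[1]) - 1)
            alleles.append(fields[2])
            present.append(fields[3] == "1")
    if n_members is None:
        raise ValueError(f"{path}: missing required '##N=' header line")
    return BeaconDB(
        n_members=n_members,
        catalog_chrom=np.array(chroms, dtype=object),
        catalog_pos=np.array(poss, dtype=np.int64),
        catalog_allele=np.array(alleles, dtype=object),
        present=np.array(present, dtype=bool),
        provenance=provenance,
        mechanism=mechanism,
    )


def import_vcf(path: str | Path) -> BeaconDB:
    """Build a beacon from a VCF with genotype (GT) fields.

    N is the sample count; a (chrom, pos, alt) triple is catalogued for
    every alt allele of every record and marked present iff at least one
    sample genotype carries that alt. Multi-allelic records are split per
    alt allele. Records without usable genotypes are skipped; the skipped
    count is logged as a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    n_samples = len(vcf.samples)
    if n_samples == 0:
        raise ValueError(f"{path}: VCF has no samples, cannot define membership")
    chroms, poss, alleles, present = [], [], [], []
    skipped = 0
    for variant in vcf:
        genotypes = variant.genotypes  # [[a1, a2, phased], ...]
        if not genotypes:
            skipped += 1
            continue
        carried = set()
        any_called = False
        for gt in genotypes:
            for allele_idx in gt[:-1]:
                if allele_idx is not None and allele_idx >= 0:
                    any_called = True
                    if allele_idx >= 1:
                        carried.add(allele_idx)
        if not any_called:
            skipped += 1
            continue
        for k, alt in enumerate(variant.ALT, start=1):
            chroms.append(variant.CHROM)
            poss.append(variant.start)  # 0-based
            alleles.append(alt)
            present.append(k in carried)
    if skipped:
        logger.warning("import_vcf: skipped %d sites without genotype calls", skipped)
    return BeaconDB(
        n_members=n_samples,
        catalog_chrom=np.array(chroms, dtype=object),
        catalog_pos=np.array(poss, dtype=np.int64),
        catalog_allele=np.array(alleles, dtype=object),
        present=np.array(present, dtype=bool),
        provenance="raw",
    )
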
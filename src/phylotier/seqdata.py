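"""Partitioned supermatrix representation, I/O and cleaning.

A *supermatrix* is a concatenated multi-gene alignment over many taxa, with
named site partitions (typically gene x codon position) and, in practice,
large fractions of missing data because not every marker has been sequenced
for every taxon.  This module holds the in-memory container used by every
downstream stage, plus readers/writers for the common text formats and the
basic hygiene operations: dropping all-missing rows/columns, codon-position
splitting, reading-frame checks, and gene-wise concatenation.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "AlignmentError",
    "Partition",
    "PartitionedAlignment",
    "CleanReport",
    "read_alignment",
    "write_alignment",
    "parse_partition_table",
    "clean_alignment",
    "split_codon_positions",
    "check_reading_frame",
    "missing_fraction",
    "concatenate",
    "extract_partition",
]

#: Characters counted as missing data by default ('N' included: supermatrix
#: gaps and undetermined bases overwhelmingly denote absent data).
DEFAULT_MISSING = frozenset({"?", "-", "N"})

#: IUPAC nucleotide ambiguity codes mapped to their state sets.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "?": "ACGT", "-": "ACGT", "X": "ACGT", "O": "ACGT",
}

STOP_CODONS = {
    "standard": {"TAA", "TAG", "TGA"},
    "vertebrate-mitochondrial": {"TAA", "TAG", "AGA", "AGG"},
}


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


@dataclass(frozen=True)
class Partition:
    """A named set of alignment sites evolving under its own model.

    ``sites`` are 0-based column indices into the parent alignment.  Coding
    partitions carry ``frame``, the ordinal offset (0/1/2) of the first
    complete codon within the partition's site list, and a genetic code used
    for stop-codon scans.
    """

    name: str
    sites: tuple[int, ...]
    origin: str | None = None  # 'mitochondrial' | 'nuclear' | None
    coding: bool = False
    frame: int | None = None
    genetic_code: str = "standard"

    def __post_init__(self):
        sites = tuple(sorted(int(s) for s in self.sites))
        object.__setattr__(self, "sites", sites)
        if len(sites) < 1:
            raise AlignmentError(f"partition {self.name!r} has no sites")
        if len(set(sites)) != len(sites):
            raise AlignmentError(f"partition {self.name!r} has repeated sites")
        if self.coding and self.frame not in (0, 1, 2):
            raise AlignmentError(
                f"coding partition {self.name!r} needs frame in {{0,1,2}}"
            )
        if self.origin not in (None, "mitochondrial", "nuclear"):
            raise AlignmentError(f"unknown origin {self.origin!r}")
        if self.genetic_code not in STOP_CODONS:
            raise AlignmentError(f"unknown genetic code {self.genetic_code!r}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


class PartitionedAlignment:
    """Taxa x sites character matrix with named, typed partitions.

    Rows are uppercase single characters over the DNA alphabet plus IUPAC
    ambiguity codes, ``-``, ``?`` and ``N``.  Partition site sets are pairwise
    disjoint subsets of ``range(L)``.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        matrix: np.ndarray | Sequence[str],
        partitions: Sequence[Partition] | None = None,
    ):
        taxa = [str(t) for t in taxa]
        if len(set(taxa)) != len(taxa):
            dup = sorted({t for t in taxa if taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon label(s): {', '.join(dup)}")
        if not isinstance(matrix, np.ndarray):
            rows = [str(r).upper() for r in matrix]
            if rows:
                lengths = {len(r) for r in rows}
                if len(lengths) > 1:
                    L0 = len(rows[0])
                    bad = next(t for t, r in zip(taxa, rows) if len(r) != L0)
                    raise AlignmentError(
                        f"ragged alignment: row for taxon {bad!r} has length "
                        f"{len(dict(zip(taxa, rows))[bad])}, expected {L0}"
                    )
            matrix = np.array([list(r) for r in rows], dtype="<U1")
            if matrix.size == 0:
                matrix = matrix.reshape(len(rows), 0)
        matrix = np.char.upper(np.asarray(matrix, dtype="<U1"))
        if matrix.ndim != 2 or matrix.shape[0] != len(taxa):
            raise AlignmentError("matrix shape does not match taxa")
        self.taxa: list[str] = taxa
        self.matrix: np.ndarray = matrix
        L = matrix.shape[1]
        if partitions is None or len(partitions) == 0:
            partitions = [Partition("all", tuple(range(L)))] if L else []
        seen: set[int] = set()
        for p in partitions:
            if p.sites and (p.sites[0] < 0 or p.sites[-1] >= L):
                raise AlignmentError(
                    f"partition {p.name!r} has site index out of range 0..{L - 1}"
                )
            overlap = seen.intersection(p.sites)
            if overlap:
                raise AlignmentError(
                    f"partition {p.name!r} overlaps earlier partitions "
                    f"at sites {sorted(overlap)[:5]}"
                )
            seen.update(p.sites)
        names = [p.name for p in partitions]
        if len(set(names)) != len(names):
            raise AlignmentError("duplicate partition names")
        self.partitions: list[Partition] = list(partitions)

    # -- basic accessors -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> str:
        try:
            i = self.taxa.index(taxon)
        except ValueError:
            raise AlignmentError(f"unknown taxon {taxon!r}") from None
        return "".join(self.matrix[i])

    def partition(self, name: str) -> Partition:
        for p in self.partitions:
            if p.name == name:
                return p
        raise AlignmentError(f"no partition named {name!r}")

    def sites_of(self, part: Partition | str) -> np.ndarray:
        if isinstance(part, str):
            part = self.partition(part)
        return np.asarray(part.sites, dtype=int)

    def block(self, part: Partition | str) -> np.ndarray:
        """Character sub-matrix (all taxa) of one partition."""
        return self.matrix[:, self.sites_of(part)]

    def copy(self) -> "PartitionedAlignment":
        return PartitionedAlignment(
            list(self.taxa), self.matrix.copy(), list(self.partitions)
        )

    def taxon_missing_fraction(self, taxon: str, missing=DEFAULT_MISSING) -> float:
        row = np.array(list(self.row(taxon)))
        return float(np.isin(row, list(missing)).mean())

    def __repr__(self):
        return (
            f"<PartitionedAlignment {self.n_taxa} taxa x {self.n_sites} sites, "
            f"{len(self.partitions)} partition(s)>"
        )

    def __eq__(self, other):
        return (
            isinstance(other, PartitionedAlignment)
            and self.taxa == other.taxa
            and self.matrix.shape == other.matrix.shape
            and bool((self.matrix == other.matrix).all())
            and self.partitions == other.partitions
        )


@dataclass
class CleanReport:
    """What :func:`clean_alignment` removed."""

    removed_taxa: list[str] = field(default_factory=list)
    removed_columns: list[int] = field(default_factory=list)
    dropped_partitions: list[str] = field(default_factory=list)

    @property
    def n_removed_columns(self) -> int:
        return len(self.removed_columns)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMAT_BY_EXT = {
    ".fa": "fasta", ".fas": "fasta", ".fasta": "fasta", ".fna": "fasta",
    ".phy": "phylip", ".phylip": "phylip",
    ".nex": "nexus", ".nexus": "nexus", ".nxs": "nexus",
}


def _sniff_format(path: Path) -> str:
    fmt = _FORMAT_BY_EXT.get(path.suffix.lower())
    if fmt:
        return fmt
    head = path.read_text().lstrip()[:10].upper()
    if head.startswith(">"):
        return "fasta"
    if head.startswith("#NEXUS"):
        return "nexus"
    return "phylip"


def read_alignment(
    path: str | Path,
    format: str | None = None,
    partition_table: str | Path | None = None,
    name: str | None = None,
) -> PartitionedAlignment:
    """Read a FASTA / relaxed-PHYLIP / NEXUS alignment.

    NEXUS ``charset`` statements are honoured; otherwise partitions come from
    ``partition_table`` (RAxML-style or tabular, see
    :func:`parse_partition_table`) or default to a single implicit partition
    named after ``name`` (or ``'all'``).
    """
    path = Path(path)
    fmt = (format or _sniff_format(path)).lower()
    partitions: list[Partition] | None = None
    if fmt in ("fasta", "phylip"):
        schema = "fasta" if fmt == "fasta" else "phylip-relaxed"
        records = list(SeqIO.parse(str(path), schema))
        if not records:
            raise AlignmentError(f"no sequences found in {path}")
        taxa = [r.id for r in records]
        rows = [str(r.seq).upper() for r in records]
        L0 = len(rows[0])
        for t, r in zip(taxa, rows):
            if len(r) != L0:
                raise AlignmentError(
                    f"ragged alignment in {path.name}: taxon {t!r} has "
                    f"{len(r)} sites, expected {L0}"
                )
    elif fmt == "nexus":
        import dendropy

        cm = dendropy.DnaCharacterMatrix.get(path=str(path), schema="nexus")
        taxa = [t.label for t in cm.taxon_namespace]
        rows = [str(cm[t]).upper() for t in cm.taxon_namespace]
        subsets = getattr(cm, "character_subsets", None) or {}
        if subsets:
            partitions = []
            for sub_name in subsets:
                idx = sorted(subsets[sub_name].character_indices)
                partitions.append(Partition(str(sub_name), tuple(idx)))
    else:
        raise AlignmentError(f"unknown alignment format {fmt!r}")

    if partition_table is not None:
        text = Path(partition_table).read_text() \
            if isinstance(partition_table, (str, Path)) and Path(partition_table).exists() \
            else str(partition_table)
        partitions = parse_partition_table(text)
    if partitions is None and name is not None and rows and rows[0]:
        partitions = [Partition(name, tuple(range(len(rows[0]))))]
    return PartitionedAlignment(taxa, rows, partitions)


def write_alignment(
    aln: PartitionedAlignment, path: str | Path, format: str | None = None
) -> None:
    """Write FASTA (wrapped), relaxed PHYLIP, or NEXUS with a SETS block."""
    path = Path(path)
    fmt = (format or _FORMAT_BY_EXT.get(path.suffix.lower(), "fasta")).lower()
    rows = {t: "".join(aln.matrix[i]) for i, t in enumerate(aln.taxa)}
    out = io.StringIO()
    if fmt == "fasta":
        for t in aln.taxa:
            out.write(f">{t}\n")
            seq = rows[t]
            for i in range(0, len(seq), 70):
                out.write(seq[i : i + 70] + "\n")
    elif fmt == "phylip":
        out.write(f"{aln.n_taxa} {aln.n_sites}\n")
        width = max(len(t) for t in aln.taxa) + 2
        for t in aln.taxa:
            out.write(t.ljust(width) + rows[t] + "\n")
    elif fmt == "nexus":
        out.write("#NEXUS\nBEGIN DATA;\n")
        out.write(f"  DIMENSIONS NTAX={aln.n_taxa} NCHAR={aln.n_sites};\n")
        out.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        width = max(len(t) for t in aln.taxa) + 2
        for t in aln.taxa:
            label = f"'{t}'" if re.search(r"\s", t) else t
            out.write("    " + label.ljust(width) + rows[t] + "\n")
        out.write("  ;\nEND;\n")
        if aln.partitions:
            out.write("BEGIN SETS;\n")
            for p in aln.partitions:
                ranges = _runs_to_nexus(p.sites)
                out.write(f"  CHARSET {p.name} = {ranges};\n")
            out.write("END;\n")
    else:
        raise AlignmentError(f"unknown alignment format {fmt!r}")
    path.write_text(out.getvalue())


def _runs_to_nexus(sites: Sequence[int]) -> str:
    """0-based indices -> NEXUS 1-based inclusive range list (with strides)."""
    sites = list(sites)
    # detect single constant stride covering all sites (common for codon sets)
    if len(sites) >= 3:
        strides = {b - a for a, b in zip(sites, sites[1:])}
        if len(strides) == 1 and strides != {1}:
            step = strides.pop()
            return f"{sites[0] + 1}-{sites[-1] + 1}\\{step}"
    parts = []
    start = prev = sites[0]
    for s in sites[1:] + [None]:
        if s is not None and s == prev + 1:
            prev = s
            continue
        parts.append(f"{start + 1}-{prev + 1}" if prev > start else f"{start + 1}")
        if s is not None:
            start = prev = s
    return " ".join(parts)


_RAXML_LINE = re.compile(r"^\s*(?:DNA|[A-Z0-9]+)\s*,\s*(\S+)\s*=\s*(.+)$", re.I)


def parse_partition_table(text: str) -> list[Partition]:
    """Parse a partition table.

    Two dialects are accepted and converted to 0-based half-open indices:

    * RAxML-style lines ``DNA, RAG1_pos1 = 12-908\\3`` (1-based inclusive,
      optional ``\\stride``, comma-separated ranges);
    * a tabular file with header columns
      ``name  start  end  stride  origin  coding  frame  code``
      (tab- or whitespace-separated; ``stride``/``origin``/... optional).
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise AlignmentError("empty partition table")
    if "=" in lines[0]:
        parts = []
        for ln in lines:
            m = _RAXML_LINE.match(ln)
            if not m:
                raise AlignmentError(f"cannot parse partition line: {ln!r}")
            pname, ranges = m.group(1), m.group(2)
            sites: list[int] = []
            for rng in ranges.split(","):
                rng = rng.strip().rstrip(";")
                m2 = re.match(r"^(\d+)\s*-\s*(\d+)(?:\\(\d+))?$", rng)
                if m2:
                    a, b = int(m2.group(1)), int(m2.group(2))
                    step = int(m2.group(3) or 1)
                    sites.extend(range(a - 1, b, step))
                elif re.match(r"^\d+$", rng):
                    sites.append(int(rng) - 1)
                else:
                    raise AlignmentError(f"cannot parse range {rng!r} in {ln!r}")
            origin = "mitochondrial" if re.search(
                r"(12S|16S|cytb|CYTB|mt|MT|ND\d|COX?\d)", pname) else None
            parts.append(Partition(pname, tuple(sites), origin=origin))
        return parts
    # tabular dialect
    header = lines[0].split()
    required = {"name", "start", "end"}
    if not required.issubset(set(h.lower() for h in header)):
        raise AlignmentError("tabular partition file needs name/start/end columns")
    cols = {h.lower(): i for i, h in enumerate(header)}
    parts = []
    for ln in lines[1:]:
        f = ln.split()
        get = lambda key, default=None: (
            f[cols[key]] if key in cols and cols[key] < len(f) else default
        )
        a, b = int(get("start")), int(get("end"))
        step = int(get("stride", 1) or 1)
        coding = str(get("coding", "0")).lower() in ("1", "true", "yes")
        frame = get("frame")
        frame = int(frame) if frame not in (None, "", ".", "NA") else (0 if coding else None)
        origin = get("origin") or None
        if origin in (".", "NA", "na"):
            origin = None
        if origin in ("mito", "mt"):
            origin = "mitochondrial"
        if origin in ("nuc", "nu"):
            origin = "nuclear"
        code = get("code") or "standard"
        if code in (".", "NA"):
            code = "standard"
        parts.append(
            Partition(get("name"), tuple(range(a - 1, b, step)), origin=origin,
                      coding=coding, frame=frame, genetic_code=code)
        )
    return parts


def write_partition_table(partitions: Iterable[Partition]) -> str:
    """Tabular partition table (the dialect parse_partition_table reads back).

    Only contiguous or constant-stride partitions can be expressed; others
    raise.
    """
    rows = ["name\tstart\tend\tstride\torigin\tcoding\tframe\tcode"]
    for p in partitions:
        s = list(p.sites)
        steps = {b - a for a, b in zip(s, s[1:])} or {1}
        if len(steps) != 1:
            raise AlignmentError(
                f"partition {p.name!r} is not expressible as start/end/stride"
            )
        step = steps.pop()
        rows.append(
            "\t".join(
                [
                    p.name, str(s[0] + 1), str(s[-1] + 1), str(step),
                    p.origin or ".", "1" if p.coding else "0",
                    str(p.frame) if p.frame is not None else ".",
                    p.genetic_code,
                ]
            )
        )
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# cleaning & codon operations
# ---------------------------------------------------------------------------

def clean_alignment(
    aln: PartitionedAlignment, missing: Iterable[str] = DEFAULT_MISSING
) -> tuple[PartitionedAlignment, CleanReport]:
    """Drop taxa whose rows, and columns, consist only of missing symbols.

    Partition site sets are re-indexed to the surviving columns; partitions
    left without sites are dropped (and reported).  A column with at least
    one determinate base is never removed.
    """
    missing = set(missing)
    is_missing = np.isin(aln.matrix, list(missing))
    keep_rows = ~is_missing.all(axis=1) if aln.n_sites else np.ones(aln.n_taxa, bool)
    keep_cols = ~is_missing[keep_rows].all(axis=0) if keep_rows.any() else \
        np.zeros(aln.n_sites, bool)
    report = CleanReport(
        removed_taxa=[t for t, k in zip(aln.taxa, keep_rows) if not k],
        removed_columns=[int(j) for j in np.nonzero(~keep_cols)[0]],
    )
    if not keep_rows.any() or not keep_cols.any():
        raise AlignmentError("alignment empty after cleaning")
    new_index = -np.ones(aln.n_sites, dtype=int)
    new_index[keep_cols] = np.arange(int(keep_cols.sum()))
    new_parts = []
    for p in aln.partitions:
        sites = tuple(int(new_index[s]) for s in p.sites if keep_cols[s])
        if sites:
            new_parts.append(replace(p, sites=sites))
        else:
            report.dropped_partitions.append(p.name)
    taxa = [t for t, k in zip(aln.taxa, keep_rows) if k]
    out = PartitionedAlignment(
        taxa, aln.matrix[np.ix_(keep_rows, keep_cols)], new_parts or None
    )
    return out, report


def split_codon_positions(
    aln: PartitionedAlignment, partition: Partition | str
) -> list[Partition]:
    """Split a coding partition into its three codon-position partitions.

    Position of the i-th site (ordinal within the partition) is
    ``((i - frame) mod 3) + 1``; trailing incomplete codons follow the same
    rule, so the three outputs always partition the parent site set.
    """
    if isinstance(partition, str):
        partition = aln.partition(partition)
    if not partition.coding:
        raise AlignmentError(f"partition {partition.name!r} is not coding")
    buckets: dict[int, list[int]] = {1: [], 2: [], 3: []}
    for i, site in enumerate(partition.sites):
        pos = ((i - partition.frame) % 3) + 1
        buckets[pos].append(site)
    out = []
    for pos in (1, 2, 3):
        if buckets[pos]:
            out.append(
                Partition(
                    f"{partition.name}_pos{pos}",
                    tuple(buckets[pos]),
                    origin=partition.origin,
                    coding=False,
                    genetic_code=partition.genetic_code,
                )
            )
    return out


def check_reading_frame(
    aln: PartitionedAlignment, partition: Partition | str
) -> dict[str, int]:
    """Count in-frame stop codons per taxon (probable frame/contamination flag).

    Codons containing any non-ACGT character are skipped; only complete
    codons starting at the partition's frame offset are scanned.
    """
    if isinstance(partition, str):
        partition = aln.partition(partition)
    if not partition.coding:
        raise AlignmentError(f"partition {partition.name!r} is not coding")
    stops = STOP_CODONS[partition.genetic_code]
    block = aln.block(partition)
    counts: dict[str, int] = {}
    f = partition.frame
    n = block.shape[1]
    for i, taxon in enumerate(aln.taxa):
        row = block[i]
        c = 0
        for start in range(f, n - 2, 3):
            codon = "".join(row[start : start + 3])
            if any(ch not in "ACGT" for ch in codon):
                continue
            if codon in stops:
                c += 1
        counts[taxon] = c
    return counts


def missing_fraction(
    aln: PartitionedAlignment, missing: Iterable[str] = DEFAULT_MISSING
) -> float:
    """Fraction of matrix cells carrying a missing symbol."""
    if aln.matrix.size == 0:
        raise AlignmentError("empty matrix has no missing fraction")
    return float(np.isin(aln.matrix, list(set(missing))).mean())


def concatenate(gene_alignments: Sequence[PartitionedAlignment]) -> PartitionedAlignment:
    """Concatenate gene alignments into a supermatrix.

    The taxon set is the union of the inputs' taxa; rows absent for a gene
    are filled with ``'?'``.  Each input contributes its partitions with
    cumulatively shifted site indices.  A partition name occurring in two
    inputs must carry identical sequences for shared taxa (else an error);
    the duplicate block is dropped.
    """
    if not gene_alignments:
        raise AlignmentError("nothing to concatenate")
    taxa: list[str] = []
    for g in gene_alignments:
        for t in g.taxa:
            if t not in taxa:
                taxa.append(t)
    seen: dict[str, tuple[PartitionedAlignment, Partition]] = {}
    blocks: list[np.ndarray] = []
    partitions: list[Partition] = []
    offset = 0
    for g in gene_alignments:
        for p in g.partitions:
            if p.name in seen:
                prev_g, prev_p = seen[p.name]
                shared = [t for t in g.taxa if t in prev_g.taxa]
                for t in shared:
                    a = "".join(prev_g.block(prev_p)[prev_g.taxa.index(t)])
                    b = "".join(g.block(p)[g.taxa.index(t)])
                    if a != b:
                        raise AlignmentError(
                            f"conflicting duplicate sequences for taxon {t!r} "
                            f"gene {p.name!r}: {a[:20]!r}... vs {b[:20]!r}..."
                        )
                continue
            seen[p.name] = (g, p)
            src = g.block(p)
            width = src.shape[1]
            block = np.full((len(taxa), width), "?", dtype="<U1")
            for i, t in enumerate(g.taxa):
                block[taxa.index(t)] = src[i]
            blocks.append(block)
            partitions.append(
                replace(p, sites=tuple(range(offset, offset + width)))
            )
            offset += width
    return PartitionedAlignment(taxa, np.hstack(blocks), partitions)


def extract_partition(
    aln: PartitionedAlignment, part: Partition | str
) -> PartitionedAlignment:
    """Single-gene alignment for one partition (taxon order preserved)."""
    if isinstance(part, str):
        part = aln.partition(part)
    block = aln.block(part)
    new_part = replace(part, sites=tuple(range(block.shape[1])))
    return PartitionedAlignment(list(aln.taxa), block, [new_part])
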
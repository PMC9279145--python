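"""Genomic file formats, genome tiling and interval bookkeeping.

Conventions used throughout the package:

* BED intervals and all internal coordinates are 0-based, half-open.
* VCF positions are 1-based on input and converted on access.
* The centre base of an even-length window ``[start, start + L)`` is the
  base at index ``start + L // 2``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenomeSequence",
    "Interval",
    "IntervalSet",
    "Window",
    "Variant",
    "Profile",
    "ProfileCompendium",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_vcf",
    "write_vcf",
    "tile_genome",
    "center_overlaps",
]

_VALID_BASES = frozenset("ACGTN")
_ASSAY_CLASSES = ("TF", "histone", "accessibility")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Core coordinate types
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """An ordered collection of contigs, alphabet restricted to A/C/G/T/N."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @property
    def names(self) -> list[str]:
        return list(self.contigs)

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self.contigs[contig]
        if start < 0 or end > len(seq):
            raise IndexError(
                f"requested [{start}, {end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]

    def base_at(self, contig: str, pos: int) -> str:
        return self.fetch(contig, pos, pos + 1)


@dataclass(frozen=True)
class Interval:
    contig: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """A list of intervals with fast point/range overlap queries.

    Queries use a per-contig merged representation built lazily; record
    order and auxiliary columns are preserved for round-tripping.
    """

    def __init__(self, records: Iterable[Interval] = ()):
        self.records: list[Interval] = list(records)
        self._index: Optional[dict[str, tuple[np.ndarray, np.ndarray]]] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.records)

    def add(self, interval: Interval) -> None:
        self.records.append(interval)
        self._index = None

    def contig_names(self) -> set[str]:
        return {r.contig for r in self.records}

    def _build_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self._index is None:
            index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            by_contig: dict[str, list[Interval]] = {}
            for rec in self.records:
                by_contig.setdefault(rec.contig, []).append(rec)
            for contig, recs in by_contig.items():
                recs.sort(key=lambda r: (r.start, r.end))
                starts: list[int] = []
                ends: list[int] = []
                for rec in recs:  # merge touching/overlapping intervals
                    if starts and rec.start <= ends[-1]:
                        ends[-1] = max(ends[-1], rec.end)
                    else:
                        starts.append(rec.start)
                        ends.append(rec.end)
                index[contig] = (np.asarray(starts), np.asarray(ends))
            self._index = index
        return self._index

    def contains(self, contig: str, pos: int) -> bool:
        """True iff the 1-bp position [pos, pos+1) lies in some interval."""
        index = self._build_index()
        if contig not in index:
            return False
        starts, ends = index[contig]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        index = self._build_index()
        if contig not in index:
            return False
        starts, ends = index[contig]
        i = int(np.searchsorted(starts, end, side="left")) - 1
        return i >= 0 and start < ends[i]

    def contains_many(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`contains` for an array of positions."""
        index = self._build_index()
        if contig not in index:
            return np.zeros(len(positions), dtype=bool)
        starts, ends = index[contig]
        i = np.searchsorted(starts, positions, side="right") - 1
        ok = i >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] < ends[i[ok]]
        return out

    def total_length(self) -> int:
        index = self._build_index()
        return int(sum((e - s).sum() for s, e in index.values()))


@dataclass(frozen=True)
class Window:
    """A fixed-length window identified by its contig and centre position."""

    contig: str
    center: int
    length: int

    @property
    def start(self) -> int:
        return self.center - self.length // 2

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class Variant:
    contig: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    af: Optional[float] = None
    id: Optional[str] = None

    def __post_init__(self) -> None:
        for allele, label in ((self.ref, "REF"), (self.alt, "ALT")):
            if not allele or set(allele) - set("ACGT"):
                raise FormatError(
                    f"invalid {label} allele {allele!r} at "
                    f"{self.contig}:{self.pos}"
                )
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise FormatError(f"AF {self.af} outside [0, 1] at {self.contig}:{self.pos}")

    @property
    def pos0(self) -> int:
        """0-based position of the first REF base."""
        return self.pos - 1

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"


# ---------------------------------------------------------------------------
# Chromatin-profile compendium
# ---------------------------------------------------------------------------


@dataclass
class Profile:
    """One peak-call profile with its assay metadata."""

    profile_id: str
    target: str
    assay_class: str
    cell_type: str
    peaks: IntervalSet = field(default_factory=IntervalSet)

    def __post_init__(self) -> None:
        if self.assay_class not in _ASSAY_CLASSES:
            raise ValueError(
                f"assay_class must be one of {_ASSAY_CLASSES}, "
                f"got {self.assay_class!r}"
            )


class ProfileCompendium:
    """An ordered collection of chromatin profiles used as model targets."""

    def __init__(self, profiles: Iterable[Profile] = ()):
        self.profiles: list[Profile] = list(profiles)
        ids = [p.profile_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate profile ids in compendium")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[Profile]:
        return iter(self.profiles)

    def __getitem__(self, i: int) -> Profile:
        return self.profiles[i]

    @property
    def ids(self) -> list[str]:
        return [p.profile_id for p in self.profiles]

    def histone_mask(self) -> np.ndarray:
        """Boolean mask over profiles flagging histone-mark assays."""
        return np.array([p.assay_class == "histone" for p in self.profiles])

    def filter_min_peaks(self, min_peaks: int = 1000) -> "ProfileCompendium":
        """Drop profiles with fewer peaks than ``min_peaks``."""
        return ProfileCompendium(
            p for p in self.profiles if len(p.peaks) >= min_peaks
        )

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "profile_id": [p.profile_id for p in self.profiles],
                "target": [p.target for p in self.profiles],
                "assay_class": [p.assay_class for p in self.profiles],
                "cell_type": [p.cell_type for p in self.profiles],
                "n_peaks": [len(p.peaks) for p in self.profiles],
            }
        )

    def write(self, directory: str) -> None:
        """Write one BED file per profile plus a metadata TSV."""
        os.makedirs(directory, exist_ok=True)
        meta = self.metadata_frame()
        meta["peak_file"] = [f"{pid}.bed" for pid in meta["profile_id"]]
        meta.to_csv(os.path.join(directory, "profiles.tsv"), sep="\t", index=False)
        for profile in self.profiles:
            write_bed(profile.peaks, os.path.join(directory, f"{profile.profile_id}.bed"))

    @classmethod
    def read(cls, directory: str) -> "ProfileCompendium":
        meta = pd.read_csv(os.path.join(directory, "profiles.tsv"), sep="\t")
        profiles = []
        for row in meta.itertuples():
            peaks = read_bed(os.path.join(directory, str(row.peak_file)))
            profiles.append(
                Profile(
                    profile_id=str(row.profile_id),
                    target=str(row.target),
                    assay_class=str(row.assay_class),
                    cell_type=str(row.cell_type),
                    peaks=peaks,
                )
            )
        return cls(profiles)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> GenomeSequence:
    """Read a (multi-)FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; ``N`` is preserved. Malformed input raises
    :class:`FormatError` naming the offending line number.
    """
    contigs: dict[str, list[str]] = {}
    current: Optional[str] = None
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if name in contigs:
                    raise FormatError(f"{path}:{lineno}: duplicate contig {name!r}")
                contigs[name] = []
                current = name
            else:
                if current is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before any FASTA header"
                    )
                chunk = line.upper()
                if set(chunk) - _VALID_BASES:
                    bad = sorted(set(chunk) - _VALID_BASES)
                    raise FormatError(
                        f"{path}:{lineno}: invalid sequence characters {bad}"
                    )
                contigs[current].append(chunk)
    return GenomeSequence({name: "".join(parts) for name, parts in contigs.items()})


def write_fasta(genome: GenomeSequence, path: str, line_width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in genome.contigs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                handle.write(seq[i : i + line_width] + "\n")


def read_bed(path: str) -> IntervalSet:
    """Read a BED3+ file (tab-delimited, 0-based half-open)."""
    records = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            try:
                records.append(Interval(contig, start, end, name=name, score=score))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(records)


def _format_score(score: Optional[float]) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(score)


def write_bed(intervals: IntervalSet, path: str) -> None:
    with open(path, "w") as handle:
        for rec in intervals:
            fields = [rec.contig, str(rec.start), str(rec.end)]
            if rec.name is not None or rec.score is not None:
                fields.append(rec.name if rec.name is not None else ".")
            if rec.score is not None:
                fields.append(_format_score(rec.score))
            handle.write("\t".join(fields) + "\n")


def read_vcf(path: str, af_key: str = "AF") -> list[Variant]:
    """Read a VCF 4.x file, splitting multi-allelic rows into one
    :class:`Variant` per ALT allele. The allele-frequency INFO key is
    configurable (per-allele values follow the ALT order)."""
    import pysam

    variants: list[Variant] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.ref is None or rec.alts is None:
                raise FormatError(
                    f"{path}: record at {rec.chrom}:{rec.pos} missing REF/ALT"
                )
            af_values = rec.info.get(af_key) if af_key in rec.info else None
            if af_values is not None and not isinstance(af_values, (tuple, list)):
                af_values = (af_values,)
            for i, alt in enumerate(rec.alts):
                af = None
                if af_values is not None and i < len(af_values):
                    af = float(af_values[i])
                variants.append(
                    Variant(
                        contig=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt),
                        af=af,
                        id=rec.id,
                    )
                )
    return variants


def write_vcf(
    variants: Sequence[Variant],
    path: str,
    contig_lengths: Optional[Mapping[str, int]] = None,
    af_key: str = "AF",
) -> None:
    """Write variants as a minimal, valid VCF 4.2 text file."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(f'##INFO=<ID={af_key},Number=A,Type=Float,Description="Allele frequency">\n')
    if contig_lengths:
        for name, length in contig_lengths.items():
            buf.write(f"##contig=<ID={name},length={length}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for v in variants:
        info = f"{af_key}={v.af:.6g}" if v.af is not None else "."
        vid = v.id if v.id is not None else "."
        buf.write(f"{v.contig}\t{v.pos}\t{vid}\t{v.ref}\t{v.alt}\t.\t.\t{info}\n")
    with open(path, "w") as handle:
        handle.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Tiling and centre-overlap
# ---------------------------------------------------------------------------


def _n_prefix(seq: str) -> np.ndarray:
    isn = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord("N")
    out = np.zeros(len(seq) + 1, dtype=np.int64)
    np.cumsum(isn, out=out[1:])
    return out


def tile_genome(
    genome: GenomeSequence,
    window_len: int,
    step: int,
    exclude: Optional[IntervalSet] = None,
    max_n_fraction: float = 0.0,
) -> list[Window]:
    """Tile every contig with centred windows at a fixed step.

    Centres are placed every ``step`` bp such that the full window lies
    within the contig. Windows overlapping ``exclude`` intervals, or whose
    N fraction exceeds ``max_n_fraction`` (default: any N), are dropped.
    Contigs shorter than ``window_len`` simply yield no windows.
    """
    if window_len % 2 != 0:
        raise ValueError("window_len must be even")
    if step < 1:
        raise ValueError("step must be >= 1")
    half = window_len // 2
    max_n = int(np.floor(max_n_fraction * window_len))
    windows: list[Window] = []
    for contig, seq in genome.contigs.items():
        clen = len(seq)
        if clen < window_len:
            continue
        centers = np.arange(half, clen - half + 1, step, dtype=np.int64)
        if centers.size == 0:
            continue
        keep = np.ones(centers.size, dtype=bool)
        if "N" in seq:
            prefix = _n_prefix(seq)
            n_counts = prefix[centers + half] - prefix[centers - half]
            keep &= n_counts <= max_n
        if exclude is not None and len(exclude):
            for i, c in enumerate(centers):
                if keep[i] and exclude.overlaps(contig, int(c) - half, int(c) + half):
                    keep[i] = False
        windows.extend(
            Window(contig, int(c), window_len) for c in centers[keep]
        )
    return windows


def center_overlaps(window: Window, peaks: IntervalSet) -> bool:
    """True iff the window's centre base lies within any peak interval."""
    return peaks.contains(window.contig, window.center)


def windows_to_bed(windows: Sequence[Window], path: str) -> None:
    with open(path, "w") as handle:
        for w in windows:
            handle.write(f"{w.contig}\t{w.start}\t{w.end}\t{w.center}\n")
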
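"""Readers and writers for local-ancestry panels and annotation formats.

The central in-memory object is the :class:`HaplotypePanel`: for every sample
in an admixed population it holds two haplotypes, each a contiguous partition
of a chromosome into ancestry-labelled tracts.  Panels are serialized in an
RFMix-v2-style ``msp`` dialect (tab-separated ancestry codes per window, one
pair of columns per sample).  Windows whose ancestry could not be confidently
assigned carry the code ``-1`` (:data:`UNASSIGNED`), emulating the removal of
local-ancestry calls below a posterior-confidence cutoff.

Coordinates are 0-based half-open throughout (BED convention).  Adjacent
windows with the same ancestry are always merged on read, so tract identity
is canonical: two panels describing the same ancestry mosaic compare equal
regardless of how finely the file windows were cut.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNASSIGNED = -1

__all__ = [
    "UNASSIGNED",
    "FormatError",
    "StructureError",
    "CodeError",
    "AncestryPalette",
    "AncestryTract",
    "HaplotypePanel",
    "GeneModel",
    "TraitGeneSet",
    "ScoreTrack",
    "read_msp",
    "write_msp",
    "read_bed",
    "read_gmt",
    "read_score_track",
]


class FormatError(ValueError):
    """A file does not conform to the declared dialect."""


class StructureError(ValueError):
    """Windows/tracts violate ordering, tiling, or overlap constraints."""


class CodeError(ValueError):
    """An ancestry code falls outside the palette (and is not UNASSIGNED)."""


@dataclass(frozen=True)
class AncestryPalette:
    """Ordered ancestry labels with contiguous integer codes 0..K-1."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("palette needs at least two ancestries")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ancestry labels must be unique")
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def K(self) -> int:
        return len(self.labels)

    @property
    def codes(self) -> range:
        return range(self.K)

    def code_of(self, label: str) -> int:
        return self.labels.index(label)

    def header_line(self) -> str:
        pairs = "\t".join(f"{lab}={i}" for i, lab in enumerate(self.labels))
        return f"#Subpopulation order/codes: {pairs}"

    @classmethod
    def from_header(cls, line: str) -> "AncestryPalette":
        prefix = "#Subpopulation order/codes:"
        if not line.startswith(prefix):
            raise FormatError(f"bad msp header line: {line[:60]!r}")
        pairs = line[len(prefix):].strip().split("\t")
        labels: dict[int, str] = {}
        for pair in pairs:
            if "=" not in pair:
                raise FormatError(f"bad subpopulation entry {pair!r}")
            lab, code = pair.rsplit("=", 1)
            try:
                labels[int(code)] = lab.strip()
            except ValueError as exc:
                raise FormatError(f"non-integer ancestry code in {pair!r}") from exc
        if sorted(labels) != list(range(len(labels))):
            raise FormatError("ancestry codes must be contiguous from 0")
        return cls(tuple(labels[i] for i in range(len(labels))))


@dataclass(frozen=True)
class AncestryTract:
    """A maximal single-ancestry segment of one haplotype."""

    chrom: str
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    ancestry: int

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise StructureError(f"empty tract [{self.start_bp}, {self.end_bp})")
        if self.start_cm > self.end_cm:
            raise StructureError("genetic positions out of order")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


def merge_tracts(tracts: Sequence[AncestryTract]) -> list[AncestryTract]:
    """Merge runs of adjacent tracts that share an ancestry code."""
    merged: list[AncestryTract] = []
    for t in tracts:
        if merged and merged[-1].ancestry == t.ancestry:
            prev = merged[-1]
            merged[-1] = AncestryTract(
                prev.chrom, prev.start_bp, t.end_bp, prev.start_cm, t.end_cm, prev.ancestry
            )
        else:
            merged.append(t)
    return merged


@dataclass
class HaplotypePanel:
    """Local-ancestry calls for one population on one chromosome.

    ``haplotypes`` holds ``2 * len(samples)`` tract lists in sample order
    (sample 0 haplotype 0, sample 0 haplotype 1, sample 1 haplotype 0, ...).
    Every haplotype exactly tiles ``chrom_span`` with no gaps or overlaps.
    """

    population: str
    samples: list[str]
    haplotypes: list[list[AncestryTract]]
    palette: AncestryPalette
    chrom: str
    chrom_span: tuple[int, int]
    _arrays: list[tuple[np.ndarray, np.ndarray]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def validate(self) -> None:
        if len(self.haplotypes) != 2 * len(self.samples):
            raise StructureError("panel must have exactly 2 haplotypes per sample")
        lo, hi = self.chrom_span
        if lo >= hi:
            raise StructureError("empty chromosome span")
        for h, tracts in enumerate(self.haplotypes):
            if not tracts:
                raise StructureError(f"haplotype {h} has no tracts")
            pos = lo
            for t in tracts:
                if t.chrom != self.chrom:
                    raise StructureError("all tracts must share the panel chromosome")
                if t.start_bp != pos:
                    kind = "gap" if t.start_bp > pos else "overlap"
                    raise StructureError(
                        f"haplotype {h}: {kind} at {pos} (tract starts {t.start_bp})"
                    )
                if not (t.ancestry == UNASSIGNED or 0 <= t.ancestry < self.palette.K):
                    raise CodeError(f"ancestry code {t.ancestry} outside palette")
                pos = t.end_bp
            if pos != hi:
                raise StructureError(f"haplotype {h} ends at {pos}, span ends at {hi}")

    def tract_arrays(self, hap_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (bounds, ancestries) for one haplotype.

        ``bounds`` has T+1 entries (tract start positions plus the span end);
        ``ancestries`` has T entries.  Cached, since scans hit this per gene.
        """
        if self._arrays is None:
            self._arrays = [
                (
                    np.fromiter(
                        (t.start_bp for t in tr), dtype=np.int64, count=len(tr)
                    ),
                    np.fromiter((t.ancestry for t in tr), dtype=np.int64, count=len(tr)),
                )
                for tr in self.haplotypes
            ]
            end = self.chrom_span[1]
            self._arrays = [
                (np.append(starts, end), anc) for starts, anc in self._arrays
            ]
        return self._arrays[hap_index]

    def merged(self) -> "HaplotypePanel":
        return HaplotypePanel(
            population=self.population,
            samples=list(self.samples),
            haplotypes=[merge_tracts(h) for h in self.haplotypes],
            palette=self.palette,
            chrom=self.chrom,
            chrom_span=self.chrom_span,
        )


@dataclass(frozen=True)
class GeneModel:
    chrom: str
    start_bp: int
    end_bp: int
    name: str

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError(f"gene {self.name}: empty interval")


@dataclass(frozen=True)
class TraitGeneSet:
    trait: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"trait {self.trait}: empty gene set")
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass(frozen=True)
class ScoreTrack:
    """Per-position selection-score track (e.g. normalized iHS)."""

    positions: np.ndarray
    scores: np.ndarray
    label: str = "score"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        sco = np.asarray(self.scores, dtype=float)
        if pos.shape != sco.shape or pos.ndim != 1:
            raise ValueError("positions and scores must be equal-length vectors")
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "scores", sco)

    def abs(self) -> "ScoreTrack":
        return ScoreTrack(self.positions, np.abs(self.scores), f"|{self.label}|")


# ---------------------------------------------------------------------------
# msp dialect


def read_msp(
    path, palette: AncestryPalette | None = None, population: str | None = None
) -> HaplotypePanel:
    """Read an RFMix-style msp file into a :class:`HaplotypePanel`.

    Window rows must be sorted, non-overlapping and gap-free; adjacent windows
    with equal ancestry are merged into maximal tracts.  The palette is taken
    from the first header line unless supplied.  ``population`` defaults to
    the file stem.
    """
    import os

    with open(path) as fh:
        line1 = fh.readline().rstrip("\n")
        line2 = fh.readline().rstrip("\n")
        header_palette = AncestryPalette.from_header(line1)
        if palette is None:
            palette = header_palette
        if not line2.startswith("#"):
            raise FormatError("missing column header line")
        cols = line2.lstrip("#").split("\t")
        if len(cols) < 6:
            raise FormatError("column header has fewer than 6 leading columns")
        hap_cols = cols[6:]
        if len(hap_cols) % 2 != 0:
            raise FormatError("odd number of haplotype columns")
        samples: list[str] = []
        for i in range(0, len(hap_cols), 2):
            a, b = hap_cols[i], hap_cols[i + 1]
            if not (a.endswith(".0") and b.endswith(".1") and a[:-2] == b[:-2]):
                raise FormatError(f"haplotype columns {a!r}/{b!r} not paired")
            samples.append(a[:-2])
        body = fh.read()

    n_hap = 2 * len(samples)
    if body.strip():
        df = pd.read_csv(
            io.StringIO(body), sep="\t", header=None, dtype={0: str}
        )
        if df.shape[1] != 6 + n_hap:
            raise FormatError(
                f"rows have {df.shape[1]} columns, expected {6 + n_hap}"
            )
    else:
        df = pd.DataFrame(columns=range(6 + n_hap))

    if population is None:
        population = os.path.basename(str(path))
        for ext in (".tsv", ".txt", ".msp"):
            if population.endswith(ext):
                population = population[: -len(ext)]

    if df.empty:
        raise StructureError("msp file has no window rows")

    chroms = df[0].astype(str).unique()
    if len(chroms) != 1:
        raise StructureError("panel must cover a single chromosome")
    chrom = chroms[0]
    spos = df[1].to_numpy(dtype=np.int64)
    epos = df[2].to_numpy(dtype=np.int64)
    sgpos = df[3].to_numpy(dtype=float)
    egpos = df[4].to_numpy(dtype=float)
    if np.any(epos <= spos):
        raise StructureError("window with non-positive length")
    if np.any(spos[1:] < epos[:-1]):
        raise StructureError("windows out of order or overlapping")
    if np.any(spos[1:] > epos[:-1]):
        raise StructureError("gap between consecutive windows")
    if np.all(sgpos == 0) and np.all(egpos == 0):
        # no genetic map in the file: impute a constant 1 cM/Mb
        sgpos = spos / 1e6
        egpos = epos / 1e6

    codes = df.iloc[:, 6:].to_numpy(dtype=np.int64)
    bad = (codes != UNASSIGNED) & ((codes < 0) | (codes >= palette.K))
    if bad.any():
        raise CodeError(
            f"ancestry codes outside palette: {sorted(set(codes[bad].tolist()))}"
        )

    span = (int(spos[0]), int(epos[-1]))
    haplotypes: list[list[AncestryTract]] = []
    for h in range(n_hap):
        col = codes[:, h]
        tracts = [
            AncestryTract(chrom, int(spos[w]), int(epos[w]), float(sgpos[w]),
                          float(egpos[w]), int(col[w]))
            for w in range(len(spos))
        ]
        haplotypes.append(merge_tracts(tracts))
    return HaplotypePanel(
        population=population,
        samples=samples,
        haplotypes=haplotypes,
        palette=palette,
        chrom=chrom,
        chrom_span=span,
    )


def write_msp(panel: HaplotypePanel, path) -> None:
    """Write a panel in the msp dialect (windows = union of tract breaks)."""
    panel.validate()
    if not panel.haplotypes:
        with open(path, "w") as fh:
            fh.write(panel.palette.header_line() + "\n")
            fh.write("#chm\tspos\tepos\tsgpos\tegpos\tn snps\n")
        return
    lo, hi = panel.chrom_span
    cut_set: set[int] = {lo, hi}
    for tracts in panel.haplotypes:
        cut_set.update(t.start_bp for t in tracts)
    cuts = np.array(sorted(cut_set), dtype=np.int64)
    starts, ends = cuts[:-1], cuts[1:]

    # genetic positions: interpolate from the first haplotype's tracts when
    # available, else constant 1 cM/Mb
    def gpos(bp: np.ndarray) -> np.ndarray:
        if panel.haplotypes:
            xs, ys = [], []
            for t in panel.haplotypes[0]:
                xs.extend([t.start_bp, t.end_bp])
                ys.extend([t.start_cm, t.end_cm])
            return np.interp(bp, xs, ys)
        return bp / 1e6

    sg, eg = gpos(starts.astype(float)), gpos(ends.astype(float))
    lines = [panel.palette.header_line()]
    hap_names = "\t".join(
        f"{s}.{h}" for s in panel.samples for h in (0, 1)
    )
    header2 = "#chm\tspos\tepos\tsgpos\tegpos\tn snps"
    lines.append(header2 + ("\t" + hap_names if hap_names else ""))

    if panel.haplotypes:
        code_cols = []
        for h in range(panel.n_haplotypes):
            bounds, anc = panel.tract_arrays(h)
            idx = np.searchsorted(bounds, starts, side="right") - 1
            code_cols.append(anc[idx])
        code_mat = np.stack(code_cols, axis=1)
    else:
        code_mat = np.zeros((len(starts), 0), dtype=np.int64)

    for w in range(len(starts)):
        row = [panel.chrom, str(int(starts[w])), str(int(ends[w])),
               f"{sg[w]:.6f}", f"{eg[w]:.6f}", "1"]
        row.extend(str(int(c)) for c in code_mat[w])
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# annotation formats


def read_bed(path) -> list[GeneModel]:
    """Read gene models from a BED4 file; gene names must be unique."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: BED4 needs 4 columns")
            chrom, start, end, name = parts[:4]
            if name in seen:
                raise FormatError(f"{path}:{ln}: duplicate gene name {name!r}")
            seen.add(name)
            genes.append(GeneModel(chrom, int(start), int(end), name))
    return genes


def read_gmt(path) -> list[TraitGeneSet]:
    """Read trait gene sets from a GMT file (trait, description, genes...)."""
    sets: list[TraitGeneSet] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT set has no genes")
            sets.append(TraitGeneSet(parts[0], parts[1], frozenset(parts[2:])))
    return sets


def read_score_track(path, dialect: str = "generic_tsv", label: str | None = None) -> ScoreTrack:
    """Read a per-position score track.

    ``selscan_norm``: selscan normalized output, 8 whitespace-separated columns
    (id, pos, freq, ihh1, ihh0, unstandardized score, standardized score,
    crit); the standardized column is taken as the score.
    ``generic_tsv``: two tab-separated columns (pos, score), optional header.
    """
    if dialect == "selscan_norm":
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
        if df.shape[1] < 7:
            raise FormatError("selscan normalized output needs >= 7 columns")
        pos = df.iloc[:, 1].to_numpy(dtype=np.int64)
        score = df.iloc[:, 6].to_numpy(dtype=float)
        label = label or "iHS"
    elif dialect == "generic_tsv":
        rows: list[tuple[int, float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, b = line.split("\t")[:2]
                try:
                    rows.append((int(a), float(b)))
                except ValueError:
                    if rows:
                        raise FormatError(f"non-numeric row {line!r}")
                    continue  # header line
        pos = np.array([r[0] for r in rows], dtype=np.int64)
        score = np.array([r[1] for r in rows], dtype=float)
        label = label or "score"
    else:
        raise ValueError(f"unknown score-track dialect {dialect!r}")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("score-track positions must be strictly increasing")
    return ScoreTrack(pos, score, label)
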
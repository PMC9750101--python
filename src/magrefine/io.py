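"""Readers and writers for the on-disk formats the tool touches.

Three inputs are understood:

* contig-to-bin mapping tables (TSV) as emitted by MetaBAT2, MaxBin2,
  CONCOCT, VAMB and friends, in either column order;
* HMMER3 per-target tables (``hmmsearch --tblout``) holding marker-gene
  annotations of predicted proteins;
* a pre-digested three/four-column marker TSV for users who annotate
  outside HMMER.

plus plain-text marker-set definition files (one marker id per line).
All identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .refine import RefinementResult

logger = logging.getLogger("magrefine")

#: header keywords recognised during contig-to-bin header auto-detection
_HEADER_KEYWORDS = {"bin", "bin_id", "contig", "contig_id", "binset", "binset_label"}


class ParseError(ValueError):
    """A malformed line in an input file; carries file and line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True)
class RawHit:
    """One raw protein-to-marker hit, prior to best-hit resolution."""

    protein_id: str
    marker_id: str
    evalue: float = 0.0
    bitscore: float = 0.0

    def __post_init__(self):
        if not self.protein_id or not self.marker_id:
            raise ValueError("protein_id and marker_id must be non-empty")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class ContigToBinRecord:
    """One (contig, bin) assignment within a named binset."""

    bin_id: str
    contig_id: str
    binset_label: str

    def __post_init__(self):
        if not (self.bin_id and self.contig_id and self.binset_label):
            raise ValueError("all ContigToBinRecord fields must be non-empty")


@dataclass(frozen=True)
class MarkerSet:
    """A named, domain-specific collection of single-copy marker identifiers."""

    name: str
    marker_ids: frozenset[str]

    def __post_init__(self):
        if not self.marker_ids:
            raise ValueError(f"marker set {self.name!r} is empty")

    @property
    def size(self) -> int:
        return len(self.marker_ids)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self.marker_ids


def read_contig_to_bin(
    path,
    binset_label: str,
    order: str = "contig_first",
) -> list[ContigToBinRecord]:
    """Read a contig-to-bin TSV into records.

    Accepts two or three tab-separated columns.  With two columns the order is
    controlled by *order* (``"contig_first"``, the DAS Tool convention, or
    ``"bin_first"``); a third column names the binset and overrides
    *binset_label*.  A first line containing a recognised column-name keyword
    is treated as a header.  Duplicate identical rows are collapsed.
    """
    if order not in ("contig_first", "bin_first"):
        raise ValueError(f"unknown column order {order!r}")
    path = Path(path)
    records: list[ContigToBinRecord] = []
    seen: set[ContigToBinRecord] = set()
    n_data = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2:
                raise ParseError(path, lineno, f"expected >=2 tab-separated columns, got {len(cells)}")
            if n_data == 0 and any(c.strip().lower() in _HEADER_KEYWORDS for c in cells[:2]):
                continue  # header line
            n_data += 1
            if order == "contig_first":
                contig_id, bin_id = cells[0].strip(), cells[1].strip()
            else:
                bin_id, contig_id = cells[0].strip(), cells[1].strip()
            label = cells[2].strip() if len(cells) >= 3 and cells[2].strip() else binset_label
            if not contig_id or not bin_id:
                raise ParseError(path, lineno, "empty contig or bin identifier")
            rec = ContigToBinRecord(bin_id=bin_id, contig_id=contig_id, binset_label=label)
            if rec not in seen:
                seen.add(rec)
                records.append(rec)
    if not records:
        logger.warning("contig-to-bin file %s contained no records", path)
    return records


def write_contig_to_bin(records: Iterable[ContigToBinRecord], path) -> None:
    """Write records as a three-column TSV (contig, bin, binset)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f"{rec.contig_id}\t{rec.bin_id}\t{rec.binset_label}\n")


def read_hmmer_tblout(path) -> list[RawHit]:
    """Parse a HMMER3 per-target table (``--tblout``) into raw hits.

    Column 1 is the target (protein), column 3 the query (marker profile),
    columns 5/6 the full-sequence E-value and bit score.  No filtering is
    applied here; best-hit selection happens downstream.
    """
    path = Path(path)
    hits: list[RawHit] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cells = line.split()
            if len(cells) < 6:
                raise ParseError(path, lineno, f"expected >=6 whitespace-separated columns, got {len(cells)}")
            try:
                evalue = float(cells[4])
                score = float(cells[5])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-numeric E-value/score field: {exc}") from None
            hits.append(RawHit(protein_id=cells[0], marker_id=cells[2], evalue=evalue, bitscore=score))
    return hits


def read_marker_tsv(path) -> list[RawHit]:
    """Parse a pre-digested marker TSV: protein, marker, bitscore[, evalue]."""
    path = Path(path)
    hits: list[RawHit] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise ParseError(path, lineno, f"expected >=3 tab-separated columns, got {len(cells)}")
            try:
                score = float(cells[2])
                evalue = float(cells[3]) if len(cells) >= 4 and cells[3].strip() else 0.0
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-numeric score/E-value field: {exc}") from None
            hits.append(RawHit(protein_id=cells[0].strip(), marker_id=cells[1].strip(),
                               evalue=evalue, bitscore=score))
    return hits


def load_marker_set(path, name: str) -> MarkerSet:
    """Load a marker-set definition: one id per line, ``#`` comments allowed."""
    path = Path(path)
    ids: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
    if not ids:
        raise ValueError(f"marker-set file {path} defines no markers")
    return MarkerSet(name=name, marker_ids=frozenset(ids))


def default_marker_sets() -> dict[str, MarkerSet]:
    """The two shipped domain marker sets, keyed by domain name.

    The shipped files carry synthetic placeholder identifiers with the
    canonical sizes (bacteria: 120, archaea: 53); see the files' comments.
    Order matters: bacteria first, which fixes the domain tie-break.
    """
    data = resources.files("magrefine.data")
    with resources.as_file(data / "bac120_synthetic_markers.txt") as p:
        bac = load_marker_set(p, "bacteria")
    with resources.as_file(data / "ar53_synthetic_markers.txt") as p:
        arc = load_marker_set(p, "archaea")
    return {"bacteria": bac, "archaea": arc}


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def write_refined_output(result: "RefinementResult", out_prefix: str) -> list[Path]:
    """Write the refinement result as three TSVs sharing *out_prefix*.

    ``<prefix>.contig_to_bin.tsv``  contig -> refined bin
    ``<prefix>.bin_scores.tsv``     one row per selected bin
    ``<prefix>.audit.tsv``          one row per refinement iteration

    Row order is deterministic: bins by descending score then id, contigs
    lexicographic within a bin, so identical runs are byte-identical.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ordered = sorted(result.selected, key=lambda pair: (-pair[1].score, pair[0].bin_id))

    c2b_path = prefix.with_name(prefix.name + ".contig_to_bin.tsv")
    with c2b_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("contig_id\trefined_bin_id\n")
        for b, _score in ordered:
            for contig in sorted(b.contigs):
                fh.write(f"{contig}\t{b.bin_id}\n")

    scores_path = prefix.with_name(prefix.name + ".bin_scores.tsv")
    with scores_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("bin_id\torigin\tbest_domain\tcompleteness\tduplicate_fraction\t"
                 "multiplicate_fraction\tscore\tn_contigs\tn_unique_markers\n")
        for b, score in ordered:
            best = score.best
            fh.write("\t".join([
                b.bin_id, b.origin, score.best_domain,
                _fmt(best.completeness), _fmt(best.duplicate_fraction),
                _fmt(best.multiplicate_fraction), _fmt(score.score),
                str(len(b.contigs)), str(best.unique_markers),
            ]) + "\n")

    audit_path = prefix.with_name(prefix.name + ".audit.tsv")
    with audit_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("iteration\twinner_id\torigin\tscore\tn_rescored\tn_pruned\tskip_applied\n")
        for rec in result.audit:
            fh.write(f"{rec.iteration}\t{rec.winner_id}\t{rec.origin}\t{_fmt(rec.score)}\t"
                     f"{rec.n_rescored}\t{rec.n_pruned}\t{str(rec.skip_applied).lower()}\n")

    return [c2b_path, scores_path, audit_path]
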
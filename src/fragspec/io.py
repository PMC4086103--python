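"""Readers and writers for every on-disk artifact.

All writers use fixed precision (m/z to 5 decimals, intensity to 2,
scores to 4), UTF-8 and Unix newlines, so outputs are diff-stable and
every writer's output re-parses to an equal in-memory object.

Peak-list dialect::

    energy0
    <mz> <intensity>
    energy1
    ...

with blocks headed ``energy0`` (low, 10V), ``energy1`` (medium, 20V) and
``energy2`` (high, 40V). The annotated variant appends a comma-separated
fragment id list to each peak line, followed by a ``fragments`` section
(``<id> <SMILES>``) and a ``transitions`` section (``<parent_id>
<child_id> <neutral_loss_formula>``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import AnnotationResult, PeakAssignment
from .chem import formula_to_string, parse_formula
from .fraggraph import FragmentationGraph
from .identify import MAX_CANDIDATES, CandidateRecord, CandidateScore
from .spectra import (
    ENERGY_HEADERS,
    ENERGY_LEVELS,
    HEADER_TO_ENERGY,
    Peak,
    Spectrum,
)


class FormatError(ValueError):
    """Malformed input text; message carries the 1-based line number."""


def _fmt_mz(x: float) -> str:
    return f"{x:.5f}"


def _fmt_intensity(x: float) -> str:
    return f"{x:.2f}"


# ---------------------------------------------------------------------------
# peak lists


def write_peaklist(spectra: dict[str, Spectrum]) -> str:
    lines = []
    for energy in ENERGY_LEVELS:
        if energy not in spectra:
            continue
        lines.append(ENERGY_HEADERS[energy])
        for p in spectra[energy].peaks:
            lines.append(f"{_fmt_mz(p.mz)} {_fmt_intensity(p.intensity)}")
    return "\n".join(lines) + "\n"


def read_peaklist(text: str, default_energy: str | None = None
                  ) -> dict[str, Spectrum]:
    """Parse 1-3 energy-headed peak blocks. Headerless text parses as a
    single spectrum when ``default_energy`` names its level."""
    if not text.strip():
        raise FormatError("empty peak list")
    blocks: dict[str, list[Peak]] = {}
    current: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line in HEADER_TO_ENERGY:
            energy = HEADER_TO_ENERGY[line]
            if energy in blocks:
                raise FormatError(f"line {lineno}: duplicate header {line!r}")
            blocks[energy] = []
            current = energy
            continue
        if current is None:
            if default_energy is None:
                raise FormatError(
                    f"line {lineno}: peak data before any energy header")
            current = default_energy
            blocks[current] = []
        parts = line.split()
        if len(parts) < 2:
            raise FormatError(f"line {lineno}: expected '<mz> <intensity>'")
        try:
            mz, intensity = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: malformed number: {line!r}") from exc
        blocks[current].append(Peak(mz, intensity))
    out = {}
    for energy, peaks in blocks.items():
        if not peaks:
            raise FormatError(f"energy block {ENERGY_HEADERS[energy]!r} is empty")
        out[energy] = Spectrum(energy, peaks)
    return out


# ---------------------------------------------------------------------------
# candidate lists


def read_candidates(text: str, cap: int | None = MAX_CANDIDATES
                    ) -> list[CandidateRecord]:
    """Whitespace-separated ``ID SMILES`` records, '#' comments allowed.
    Duplicate ids and (by default) more than 100 records are errors;
    unparsable SMILES are flagged on the record, not fatal."""
    if not text.strip():
        raise FormatError("empty candidate list")
    records: list[CandidateRecord] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"line {lineno}: expected 'ID SMILES'")
        ref_id, smiles = parts
        if ref_id in seen:
            raise FormatError(f"line {lineno}: duplicate reference id {ref_id!r}")
        seen.add(ref_id)
        records.append(CandidateRecord.from_line(ref_id, smiles))
    if cap is not None and len(records) > cap:
        raise FormatError(
            f"candidate list has {len(records)} records; at most {cap} "
            f"candidates are allowed")
    return records


def write_candidates(records: list[CandidateRecord]) -> str:
    return "".join(f"{r.ref_id} {r.smiles}\n" for r in records)


# ---------------------------------------------------------------------------
# fragmentation graphs


def write_graph(graph: FragmentationGraph) -> str:
    """Transition-list serialization: node lines ``id ion_mass SMILES``,
    then edge lines ``parent_id child_id neutral_loss_formula``."""
    lines = [f"{n.id} {_fmt_mz(n.ion_mass)} {n.smiles}" for n in graph.nodes]
    lines += [
        f"{t.parent_id} {t.child_id} {formula_to_string(t.neutral_loss_formula)}"
        for t in graph.transitions
    ]
    return "\n".join(lines) + "\n"


@dataclass
class SerializedGraph:
    """The information content of a graph text file: ids, masses and
    skeleton SMILES per node; (parent, child, loss formula) per edge."""

    nodes: list[tuple[int, float, str]]
    transitions: list[tuple[int, int, dict[str, int]]]


def read_graph(text: str) -> SerializedGraph:
    nodes = []
    transitions = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(f"line {lineno}: expected 3 fields")
        try:
            second_is_int = parts[1].isdigit() and "." not in parts[1]
            if second_is_int:
                transitions.append(
                    (int(parts[0]), int(parts[1]), parse_formula(parts[2])))
            else:
                nodes.append((int(parts[0]), float(parts[1]), parts[2]))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    return SerializedGraph(nodes, transitions)


# ---------------------------------------------------------------------------
# annotation files


@dataclass
class AnnotationDocument:
    """Parsed annotation file: peak lines with fragment id lists per
    energy, the id -> SMILES fragment table, and the transition list."""

    peaks: dict[str, list[tuple[float, float, list[int]]]]
    fragments: list[tuple[int, str]] = field(default_factory=list)
    transitions: list[tuple[int, int, dict[str, int]]] = field(default_factory=list)


def write_annotation_file(result: AnnotationResult) -> str:
    lines = []
    for energy in ENERGY_LEVELS:
        if energy not in result.assignments:
            continue
        lines.append(ENERGY_HEADERS[energy])
        for pa in result.assignments[energy]:
            ids = ",".join(str(fid) for fid, _ in pa.candidates)
            base = f"{_fmt_mz(pa.peak.mz)} {_fmt_intensity(pa.peak.intensity)}"
            lines.append(f"{base} {ids}" if ids else base)
    lines.append("fragments")
    for n in result.pruned_graph.nodes:
        lines.append(f"{n.id} {n.smiles}")
    lines.append("transitions")
    for t in result.pruned_graph.transitions:
        lines.append(f"{t.parent_id} {t.child_id} "
                     f"{formula_to_string(t.neutral_loss_formula)}")
    return "\n".join(lines) + "\n"


def read_annotation_file(text: str) -> AnnotationDocument:
    peaks: dict[str, list[tuple[float, float, list[int]]]] = {}
    fragments: list[tuple[int, str]] = []
    transitions: list[tuple[int, int, dict[str, int]]] = []
    section = "peaks"
    current: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line in HEADER_TO_ENERGY:
            current = HEADER_TO_ENERGY[line]
            peaks[current] = []
            continue
        if line == "fragments":
            section = "fragments"
            continue
        if line == "transitions":
            section = "transitions"
            continue
        parts = line.split()
        try:
            if section == "peaks":
                if current is None:
                    raise FormatError(
                        f"line {lineno}: peak data before any energy header")
                ids = [int(t) for t in parts[2].split(",")] if len(parts) > 2 else []
                peaks[current].append((float(parts[0]), float(parts[1]), ids))
            elif section == "fragments":
                fragments.append((int(parts[0]), parts[1]))
            else:
                transitions.append(
                    (int(parts[0]), int(parts[1]), parse_formula(parts[2])))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"line {lineno}: malformed line {line!r}") from exc
    return AnnotationDocument(peaks, fragments, transitions)


# ---------------------------------------------------------------------------
# identification output


def write_identify_tsv(scores: list[CandidateScore]) -> str:
    lines = ["rank\tref_id\tscore\tsmiles"]
    lines += [f"{s.rank}\t{s.ref_id}\t{s.score:.4f}\t{s.smiles}" for s in scores]
    return "\n".join(lines) + "\n"


def read_identify_tsv(text: str) -> list[CandidateScore]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != "rank\tref_id\tscore\tsmiles":
        raise FormatError("missing identify TSV header")
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"line {lineno}: expected 4 tab-separated fields")
        out.append(CandidateScore(parts[1], parts[3], float(parts[2]),
                                  int(parts[0])))
    return out
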
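"""Readers and writers for the package's plain-text formats.

All tabular formats are TSV with ``#``-prefixed metadata/comment lines;
sequences travel as FASTA (wrapped at 80 columns on write, any wrapping
accepted on read).  Floats are written with ``%.17g`` so that every writer's
output parses back to an identical in-memory value and diffs are stable
across runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .kmer import KmerEnergyTable, all_kmers, encode, kmer_code
from .model import ScoreEvaluation, ScoreTable
from .positioning import Segment, TranscriptAnnotation
from .simulate import LibraryParams, ReporterLibrary

FLOAT_FMT = "%.17g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % float(x)


def sha256_of(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


# -- FASTA ------------------------------------------------------------------

def write_fasta(sequences, path, wrap: int = 80) -> None:
    """Write (id, sequence) pairs as FASTA, wrapped at ``wrap`` columns."""
    records = (SeqRecord(Seq(seq), id=str(name), description="") for name, seq in sequences)
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=wrap)
        writer.write_file(records)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) pairs, preserving order."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


# -- energy / score tables --------------------------------------------------

def write_energy_table(table: KmerEnergyTable, path, comments: dict | None = None) -> None:
    """Two-column TSV ``kmer<TAB>delta_g``, lexicographic word order."""
    with open(path, "w") as handle:
        for key, value in (comments or {}).items():
            handle.write(f"# {key}={value}\n")
        handle.write("kmer\tdelta_g\n")
        for word, value in zip(all_kmers(table.k), table.values):
            handle.write(f"{word}\t{_fmt(value)}\n")


def read_energy_table(path, k: int | None = None) -> KmerEnergyTable:
    """Read a ``kmer<TAB>delta_g`` TSV; words absent from the file get 0.

    ``k`` is inferred from the first word when not given.
    """
    entries: dict[str, float] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "kmer":  # header
                continue
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
            word, raw = fields
            try:
                value = float(raw)
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: bad energy {raw!r}") from err
            if k is None:
                k = len(word)
            entries[word] = value
    if k is None:
        raise ValueError(f"{path}: no k-mer rows found")
    return KmerEnergyTable.from_dict(k, entries)


def write_score_table(scores: ScoreTable, path) -> None:
    """TSV ``kmer<TAB>score<TAB>log_score`` with metadata comment lines."""
    with open(path, "w") as handle:
        handle.write(f"# k={scores.k}\n")
        handle.write(f"# method={scores.method}\n")
        if scores.pseudocount is not None:
            handle.write(f"# pseudocount={_fmt(scores.pseudocount)}\n")
        handle.write("kmer\tscore\tlog_score\n")
        for word, s, ls in zip(all_kmers(scores.k), scores.scores, scores.log_scores):
            handle.write(f"{word}\t{_fmt(s)}\t{_fmt(ls)}\n")


def read_score_table(path) -> ScoreTable:
    meta: dict[str, str] = {}
    k: int | None = None
    values: np.ndarray | None = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key] = val
                continue
            fields = line.split("\t")
            if fields[0] == "kmer":
                continue
            if len(fields) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns, got {len(fields)}")
            word = fields[0]
            if k is None:
                k = int(meta.get("k", len(word)))
                values = np.ones(4**k)
            try:
                values[kmer_code(word, k)] = float(fields[1])
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: bad score {fields[1]!r}") from err
    if k is None or values is None:
        raise ValueError(f"{path}: no score rows found")
    pc = meta.get("pseudocount")
    return ScoreTable(
        k, values, method=meta.get("method", "unspecified"),
        pseudocount=None if pc is None else float(pc),
    )


# -- transcript annotations -------------------------------------------------

def write_annotation(transcript: TranscriptAnnotation, path) -> None:
    """BED-like TSV ``name<TAB>start<TAB>end<TAB>label`` per segment."""
    with open(path, "w") as handle:
        handle.write("# name\tstart\tend\tlabel\n")
        for seg in transcript.segments:
            handle.write(f"{transcript.name}\t{seg.start}\t{seg.end}\t{seg.label}\n")


def read_annotation(path, sequence: str, name: str | None = None) -> TranscriptAnnotation:
    """Read a segment TSV and attach it to a sequence.

    Raises ``ValueError`` (with the offending line) on malformed rows, and
    re-raises the :class:`TranscriptAnnotation` validation errors (gaps,
    overlaps, non-alternating labels) on structurally invalid annotations.
    """
    segments: list[Segment] = []
    seen_name = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns, got {len(fields)}")
            row_name, start, end, label = fields
            if name is not None and row_name != name:
                continue
            if seen_name is None:
                seen_name = row_name
            elif row_name != seen_name:
                raise ValueError(
                    f"{path}: line {lineno}: multiple transcript names "
                    f"({seen_name!r}, {row_name!r}); pass name= to select one"
                )
            try:
                segments.append(Segment(int(start), int(end), label))
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: {err}") from err
    if not segments:
        raise ValueError(f"{path}: no segments found" + (f" for {name!r}" if name else ""))
    return TranscriptAnnotation(sequence, segments, name=seen_name)


def write_landscape(landscape: np.ndarray, path, orientation: str) -> None:
    """TSV ``position<TAB>energy_kT`` of a per-cut-point energy profile."""
    with open(path, "w") as handle:
        handle.write(f"# orientation={orientation}\n")
        handle.write("position\tenergy_kT\n")
        for pos, energy in enumerate(landscape):
            handle.write(f"{pos}\t{_fmt(energy)}\n")


# -- reporter libraries -----------------------------------------------------

COUNTS_COLUMNS = ("reporter_id", "reads_up", "reads_down", "true_delta_g", "true_p_up")


def write_library(library: ReporterLibrary, out_dir, basename: str = "library"):
    """Write a library as FASTA + counts TSV + JSON parameter sidecar.

    Returns the three paths (fasta, counts, params).  Output is a pure
    function of the library contents, so identical libraries produce
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / f"{basename}.fasta"
    counts_path = out_dir / f"{basename}.counts.tsv"
    params_path = out_dir / f"{basename}.params.json"

    write_fasta(((i, seq) for i, seq in enumerate(library.regions)), fasta_path)
    with open(counts_path, "w") as handle:
        handle.write("\t".join(COUNTS_COLUMNS) + "\n")
        for i in range(len(library)):
            handle.write(
                f"{i}\t{library.reads_upstream[i]}\t{library.reads_downstream[i]}"
                f"\t{_fmt(library.true_delta_g[i])}\t{_fmt(library.true_p_upstream[i])}\n"
            )
    with open(params_path, "w") as handle:
        json.dump(vars(library.params) | {"format": "specklesplice.library/1"},
                  handle, indent=2, sort_keys=True)
        handle.write("\n")
    return fasta_path, counts_path, params_path


def read_counts(path) -> dict[str, np.ndarray]:
    """Parse a counts TSV, reporting the first malformed line."""
    ids, up, down, dg, p = [], [], [], [], []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == COUNTS_COLUMNS[0]:
                if tuple(fields) != COUNTS_COLUMNS:
                    raise ValueError(
                        f"{path}: line {lineno}: bad header {fields!r}, "
                        f"expected {list(COUNTS_COLUMNS)}"
                    )
                continue
            if len(fields) != len(COUNTS_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(COUNTS_COLUMNS)} "
                    f"columns, got {len(fields)}"
                )
            try:
                ids.append(fields[0])
                up.append(int(fields[1]))
                down.append(int(fields[2]))
                dg.append(float(fields[3]))
                p.append(float(fields[4]))
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: {err}") from err
    if not ids:
        raise ValueError(f"{path}: no count rows found")
    return {
        "reporter_id": np.array(ids),
        "reads_up": np.array(up, dtype=np.int64),
        "reads_down": np.array(down, dtype=np.int64),
        "true_delta_g": np.array(dg),
        "true_p_up": np.array(p),
    }


def read_library(
    fasta_path, counts_path, params_path=None, truth_table: KmerEnergyTable | None = None
) -> ReporterLibrary:
    """Re-assemble a :class:`ReporterLibrary` from its on-disk form."""
    records = read_fasta(fasta_path)
    if not records:
        raise ValueError(f"{fasta_path}: no sequences found")
    counts = read_counts(counts_path)
    if len(records) != len(counts["reporter_id"]):
        raise ValueError(
            f"{counts_path}: {len(counts['reporter_id'])} count rows but "
            f"{fasta_path} has {len(records)} sequences"
        )
    fasta_ids = [rid for rid, _ in records]
    if fasta_ids != list(counts["reporter_id"]):
        raise ValueError(f"{counts_path}: reporter ids do not match {fasta_path} record order")
    lengths = {len(seq) for _, seq in records}
    if len(lengths) != 1:
        raise ValueError(f"{fasta_path}: region lengths are not homogeneous: {sorted(lengths)}")

    codes = np.stack([encode(seq) for _, seq in records])
    if params_path is not None and Path(params_path).exists():
        with open(params_path) as handle:
            raw = json.load(handle)
        params = LibraryParams(
            n_reporters=raw["n_reporters"],
            region_length=raw["region_length"],
            reads_per_reporter=raw["reads_per_reporter"],
            seed=raw["seed"],
            k=raw["k"],
            kT=raw["kT"],
            table_id=raw["table_id"],
        )
    else:
        reads_total = int((counts["reads_up"] + counts["reads_down"]).max())
        params = LibraryParams(
            n_reporters=len(records),
            region_length=codes.shape[1],
            reads_per_reporter=reads_total,
            seed=None,
            k=min(6, codes.shape[1]),
            kT=1.0,
            table_id="unknown",
        )
    return ReporterLibrary(
        codes,
        counts["true_delta_g"],
        counts["true_p_up"],
        counts["reads_up"],
        counts["reads_down"],
        params,
        truth_table=truth_table,
    )


# -- evaluations ------------------------------------------------------------

def write_evaluation(evaluation: ScoreEvaluation, path) -> None:
    """Per-reporter prediction TSV with all metrics/filters as ``#`` headers."""
    with open(path, "w") as handle:
        for line in evaluation.header_lines():
            handle.write(line + "\n")
        has_true = evaluation.true_log_ratio is not None
        cols = ["predicted_log_ratio", "observed_log_ratio"] + (
            ["true_log_ratio"] if has_true else []
        )
        handle.write("\t".join(cols) + "\n")
        for i in range(evaluation.n_reporters):
            row = [_fmt(evaluation.predicted_log_ratio[i]), _fmt(evaluation.observed_log_ratio[i])]
            if has_true:
                row.append(_fmt(evaluation.true_log_ratio[i]))
            handle.write("\t".join(row) + "\n")


# -- run manifests ----------------------------------------------------------

def write_manifest(path, subcommand: str, parameters: dict, inputs: dict, outputs: dict) -> None:
    """JSON manifest capturing parameters, seed, and file checksums.

    Input/output files are recorded by basename with their SHA-256, so a
    re-run with the same seed produces a byte-identical manifest.
    """
    from . import __version__

    data = {
        "tool": "specklesplice",
        "version": __version__,
        "subcommand": subcommand,
        "parameters": {key: parameters[key] for key in sorted(parameters)},
        "inputs": {Path(p).name: sha256_of(p) for p in inputs.values()},
        "outputs": {Path(p).name: sha256_of(p) for p in outputs.values()},
    }
    with open(path, "w") as handle:
        json.dump(data, handle, indent=2, sort_keys=True)
        handle.write("\n")
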
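"""File formats: FASTA/FASTQ sequence input, edge-list TSV and GFA1 graphs,
bubble TSV/FASTA output, and the run-configuration echo.

Conventions: data goes to files or standard output, diagnostics to the
``debubble`` logger (standard error under the CLI).  All writers serialize
deterministically (sorted by vertex id / canonical bubble key), so a rerun
with the same configuration is byte-identical.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import asdict, dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

from .bubbles import Bubble
from .graph import Weight, WeightedDigraph

log = logging.getLogger(__name__)

__all__ = ["read_sequences", "read_graph_tsv", "write_graph_tsv",
           "read_gfa", "write_gfa", "write_bubbles", "RunConfig"]


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(path: str | Path) -> list[str]:
    """Read FASTA or FASTQ (gzip-transparent; format sniffed from the first
    byte), upper-casing sequences and dropping all-N records."""
    handle = _open_text(path)
    with handle:
        first = handle.read(1)
        handle.seek(0)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        elif first == "":
            log.warning("%s: empty sequence file", path)
            return []
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (first byte {first!r})")
        seqs = []
        dropped = 0
        for record in SeqIO.parse(handle, fmt):
            seq = str(record.seq).upper()
            if seq and set(seq) == {"N"}:
                dropped += 1
                continue
            seqs.append(seq)
    if dropped:
        log.warning("%s: dropped %d all-N record(s)", path, dropped)
    return seqs


def _parse_weight(text: str, where: str) -> Weight:
    try:
        if "/" in text or "." in text:
            w = Fraction(text)
            return int(w) if w.denominator == 1 else w
        return int(text)
    except ValueError as exc:
        raise ValueError(f"{where}: bad weight {text!r}") from exc


def read_graph_tsv(path: str | Path,
                   labels_path: str | Path | None = None) -> WeightedDigraph:
    """Edge-list TSV: one arc per line ``u<TAB>v<TAB>weight``, ``#`` comments,
    vertex names arbitrary strings mapped to dense ids in first-seen order.

    An optional sidecar TSV ``vertex<TAB>label`` attaches sequence labels.
    Duplicate arcs and negative weights are rejected with their line
    number; self-loops are pruned with a warning.
    """
    names: dict[str, int] = {}
    arcs: list[tuple[int, int, Weight]] = []
    seen: set[tuple[int, int]] = set()
    loops = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            uname, vname, wtext = parts
            w = _parse_weight(wtext, f"{path}:{lineno}")
            if w < 0:
                raise ValueError(f"{path}:{lineno}: negative weight {w}")
            u = names.setdefault(uname, len(names))
            v = names.setdefault(vname, len(names))
            if u == v:
                loops += 1
                continue
            if (u, v) in seen:
                raise ValueError(f"{path}:{lineno}: duplicate arc {uname}->{vname}")
            seen.add((u, v))
            arcs.append((u, v, w))
    if loops:
        log.warning("%s: pruned %d self-loop(s)", path, loops)
    labels = [name for name, _ in sorted(names.items(), key=lambda kv: kv[1])]
    if labels_path is not None:
        label_map: dict[str, str] = {}
        with _open_text(labels_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                try:
                    vname, lab = line.split("\t")
                except ValueError as exc:
                    raise ValueError(f"{labels_path}:{lineno}: expected 2 fields") from exc
                label_map[vname] = lab
        labels = [label_map.get(name, name) for name in labels]
    return WeightedDigraph(len(names), arcs, labels=labels)


def write_graph_tsv(g: WeightedDigraph, path: str | Path) -> None:
    """Deterministic edge-list serialization, arcs sorted by (tail, head)."""
    with open(path, "wt") as fh:
        fh.write("# u\tv\tweight\n")
        for u, v, w in sorted(g.arcs()):
            fh.write(f"{g.label_of(u)}\t{g.label_of(v)}\t{w}\n")


def write_gfa(g: WeightedDigraph, path: str | Path, k: int) -> None:
    """GFA1 with one S-line per vertex (its label as the segment sequence)
    and one L-line per arc with a ``(k-1)M`` overlap CIGAR."""
    overlap = k - 1
    with open(path, "wt") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for v in g.vertices():
            fh.write(f"S\t{v}\t{g.label_of(v)}\n")
        for u, v, _ in sorted(g.arcs()):
            fh.write(f"L\t{u}\t+\t{v}\t+\t{overlap}M\n")


def read_gfa(path: str | Path) -> tuple[WeightedDigraph, int]:
    """Read a GFA1 graph written by :func:`write_gfa`; returns the graph and
    the inferred k (overlap + 1).  Arc weights are re-derived from labels:
    ``weight(u, v) = len(label(v)) - (k - 1)``."""
    labels: dict[str, str] = {}
    links: list[tuple[str, str, int]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0] in ("H", ""):
                continue
            if parts[0] == "S":
                labels[parts[1]] = parts[2]
            elif parts[0] == "L":
                if parts[2] != "+" or parts[4] != "+":
                    raise ValueError(f"{path}:{lineno}: only + orientations supported")
                cigar = parts[5]
                if not cigar.endswith("M"):
                    raise ValueError(f"{path}:{lineno}: unsupported overlap {cigar!r}")
                links.append((parts[1], parts[3], int(cigar[:-1])))
    names = sorted(labels)
    idx = {name: i for i, name in enumerate(names)}
    overlaps = {ov for _, _, ov in links}
    if len(overlaps) > 1:
        raise ValueError(f"{path}: mixed overlap lengths {sorted(overlaps)}")
    k = (overlaps.pop() if overlaps else max((len(s) for s in labels.values()), default=1) - 1) + 1
    arcs = [(idx[a], idx[b], len(labels[b]) - (k - 1)) for a, b, _ in links]
    g = WeightedDigraph(len(names), arcs, labels=[labels[n] for n in names])
    return g, k


def _path_sequence(g: WeightedDigraph, path: Iterable[int], k: int) -> str:
    """Spell the DNA sequence of a path of labelled vertices, removing the
    (k-1)-overlaps between consecutive labels."""
    seq = ""
    for v in path:
        lab = g.label_of(v)
        seq = lab if not seq else seq + lab[k - 1:]
    return seq


def write_bubbles(bubbles: Iterable[Bubble], g: WeightedDigraph,
                  tsv: IO[str] | None = None,
                  fasta: IO[str] | None = None, k: int | None = None,
                  stopped: str | None = None) -> int:
    """Write bubbles as TSV (always) and FASTA (when the graph has labels
    and ``k`` is given).  Rows are sorted by (source, canonical key); the
    TSV footer records the bubble count and which stop condition fired, if
    any.  Returns the number of bubbles written."""
    rows = sorted(bubbles, key=lambda b: (b.s, b.key()))
    if tsv is not None:
        tsv.write("s\tt\tlen1\tlen2\tpath1\tpath2\n")
        for b in rows:
            tsv.write("\t".join((
                g.label_of(b.s), g.label_of(b.t), str(b.len1), str(b.len2),
                ",".join(g.label_of(v) for v in b.path1),
                ",".join(g.label_of(v) for v in b.path2))) + "\n")
        tsv.write(f"# bubbles={len(rows)} stopped={stopped or 'none'}\n")
    if fasta is not None:
        if g.labels is None or k is None:
            raise ValueError("FASTA output needs vertex labels and k")
        for i, b in enumerate(rows):
            fasta.write(f">bubble{i}_upper\n{_path_sequence(g, b.path1, k)}\n")
            fasta.write(f">bubble{i}_lower\n{_path_sequence(g, b.path2, k)}\n")
    return len(rows)


@dataclass
class RunConfig:
    """Full parameter echo written next to every CLI run's outputs; feeding
    it back (`--config`) reproduces the outputs byte-identically."""

    subcommand: str
    parameters: dict = field(default_factory=dict)
    tool: str = "debubble"
    version: str = "0.1.0"
    timestamp: str | None = None

    def write(self, path: str | Path) -> None:
        from datetime import datetime, timezone
        record = asdict(self)
        if record["timestamp"] is None:
            record["timestamp"] = datetime.now(timezone.utc).isoformat()
        with open(path, "wt") as fh:
            json.dump(record, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(subcommand=data["subcommand"], parameters=data["parameters"],
                   tool=data.get("tool", "debubble"),
                   version=data.get("version", "unknown"),
                   timestamp=data.get("timestamp"))
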
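"""Readers, writers, and promoter motif scanning.

Expression matrices are delimited text, probes in rows (first column holds
probe ids), samples in columns (header row holds sample ids). Orientation
is never auto-detected — silently transposing a matrix is a classic failure
mode — so callers must supply data in this layout.

Promoter sequences come as plain FASTA; target capability is assigned by
scanning each promoter for an IUPAC motif (default the canonical bHLH
G-box, CACGTG, which is its own reverse complement) on either strand.

Network outputs are written as an edge-list TSV, Cytoscape SIF, GraphML,
and a per-node degree table (isolated probes reported as NA).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .core import ExpressionMatrix, MIN_SAMPLES
from .network import DirectedNetwork, RegulationEdge, RoleTable
from .simulate import NetworkSpec

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_role_table",
    "write_role_table",
    "read_promoters",
    "scan_gbox",
    "write_edge_list",
    "read_edge_list",
    "write_sif",
    "write_graphml",
    "write_degree_table",
    "read_network_spec",
    "write_network_spec",
]

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["source", "target", "step", "statistic_kind", "value",
                "p_value", "forward_p", "reverse_p"]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path,
                           delimiter: str = "\t") -> ExpressionMatrix:
    """Load a probes x samples matrix from delimited text.

    Probes with any missing value are dropped with a logged count; duplicate
    probe ids, non-numeric cells, and fewer than 5 samples are errors.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0,
                     float_precision="round_trip")
    if df.shape[1] < MIN_SAMPLES:
        raise ValueError(f"{path}: only {df.shape[1]} samples; "
                         f"need at least {MIN_SAMPLES}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell: {exc}") from exc
    return ExpressionMatrix(df.index, df.columns, df.to_numpy())


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            delimiter: str = "\t") -> None:
    # %.17g keeps write -> read round trips bit-identical
    matrix.to_dataframe().to_csv(path, sep=delimiter, index_label="probe_id",
                                 float_format="%.17g")


# ---------------------------------------------------------------------------
# Role tables and promoter scanning
# ---------------------------------------------------------------------------

def read_role_table(path: str | Path) -> RoleTable:
    """TSV with columns probe_id, source_capable, target_capable (0/1)."""
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "source_capable", "target_capable"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return RoleTable.from_dataframe(df)


def write_role_table(roles: RoleTable, path: str | Path) -> None:
    df = roles.to_dataframe()
    df[["source_capable", "target_capable"]] = df[
        ["source_capable", "target_capable"]].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_promoters(path: str | Path) -> dict[str, str]:
    """Promoter FASTA -> {record id: uppercase sequence}."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"{path}: no FASTA records")
    return seqs


def _motif_regex(motif: str) -> re.Pattern[str]:
    try:
        return re.compile("".join(IUPAC[c] for c in motif.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc} in motif "
                         f"{motif!r}") from None


def scan_gbox(promoters: Mapping[str, str],
              motif: str = "CACGTG") -> dict[str, bool]:
    """Flag promoters containing the motif on either strand.

    Returns ``{probe_id: target_capable}``. The default G-box is
    palindromic, so both strands agree; for non-palindromic IUPAC motifs
    the reverse complement is scanned as well.
    """
    pattern = _motif_regex(motif)
    rc = str(Seq(motif.upper()).reverse_complement())
    rc_pattern = _motif_regex(rc)
    hits: dict[str, bool] = {}
    for probe, seq in promoters.items():
        if not seq:
            raise ValueError(f"empty sequence for {probe!r}")
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid characters {sorted(bad)} in "
                             f"sequence for {probe!r}")
        hits[probe] = bool(pattern.search(seq)
                           or (rc != motif.upper() and rc_pattern.search(seq)))
    n_hits = sum(hits.values())
    logger.info("motif %s found in %d of %d promoters", motif, n_hits,
                len(hits))
    return hits


def count_motif_occurrences(seq: str, motif: str = "CACGTG") -> int:
    """Number of (possibly overlapping) motif matches on the given strand."""
    pattern = _motif_regex(motif)
    return sum(1 for _ in pattern.finditer(seq.upper(), 0))


# ---------------------------------------------------------------------------
# Network writers / readers
# ---------------------------------------------------------------------------

def write_edge_list(net: DirectedNetwork, path: str | Path) -> None:
    rows = [(e.source, e.target, e.step, e.statistic_kind, e.value,
             e.p_value, e.forward_p, e.reverse_p) for e in net.edges]
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t",
                                                    index=False)


def read_edge_list(path: str | Path) -> DirectedNetwork:
    df = pd.read_csv(path, sep="\t")
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    edges = [RegulationEdge(source=str(r.source), target=str(r.target),
                            step=int(r.step),
                            statistic_kind=str(r.statistic_kind),
                            value=float(r.value), p_value=float(r.p_value),
                            forward_p=float(r.forward_p),
                            reverse_p=float(r.reverse_p))
             for r in df.itertuples(index=False)]
    nodes = sorted({n for e in edges for n in (e.source, e.target)})
    return DirectedNetwork(nodes=nodes, edges=edges, origin="assembled")


def write_sif(net: DirectedNetwork, path: str | Path,
              relation: str = "regulates") -> None:
    with open(path, "w") as fh:
        for e in net.edges:
            fh.write(f"{e.source}\t{relation}\t{e.target}\n")
        connected = {n for e in net.edges for n in (e.source, e.target)}
        for n in net.nodes:
            if n not in connected:
                fh.write(f"{n}\n")


def write_graphml(net: DirectedNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_networkx(), str(path))


def write_degree_table(net: DirectedNetwork, path: str | Path,
                       all_probes: Iterable[str] | None = None) -> None:
    """Degree table TSV; probes absent from the network get NA degrees."""
    g = net.to_networkx()
    probes = list(all_probes) if all_probes is not None else sorted(g.nodes)
    connected = {n for e in net.edges for n in (e.source, e.target)}
    rows = []
    for p in probes:
        if p in connected:
            rows.append((p, g.in_degree(p), g.out_degree(p),
                         g.in_degree(p) + g.out_degree(p)))
        else:
            rows.append((p, "NA", "NA", "NA"))
    pd.DataFrame(rows, columns=["probe_id", "in.degree", "out.degree",
                                "total.degree"]).to_csv(path, sep="\t",
                                                        index=False)


# ---------------------------------------------------------------------------
# Simulator topology files
# ---------------------------------------------------------------------------

def read_network_spec(path: str | Path) -> NetworkSpec:
    """Parse the declarative topology format.

    Lines (blank lines and ``#`` comments ignored)::

        root A11
        independent B
        edge A11 A21 0.9
    """
    roots: list[str] = []
    indep: list[str] = []
    edges: list[tuple[str, str, float]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        kind = parts[0].lower()
        if kind == "root" and len(parts) == 2:
            roots.append(parts[1])
        elif kind == "independent" and len(parts) == 2:
            indep.append(parts[1])
        elif kind == "edge" and len(parts) == 4:
            edges.append((parts[1], parts[2], float(parts[3])))
        else:
            raise ValueError(f"{path}:{lineno}: cannot parse {raw!r}")
    return NetworkSpec(root_nodes=tuple(roots),
                       independent_nodes=tuple(indep),
                       edges=tuple(edges))


def write_network_spec(spec: NetworkSpec, path: str | Path) -> None:
    lines = [f"root {r}" for r in spec.root_nodes]
    lines += [f"independent {i}" for i in spec.independent_nodes]
    lines += [f"edge {s} {t} {b:g}" for s, t, b in spec.edges]
    Path(path).write_text("\n".join(lines) + "\n")
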
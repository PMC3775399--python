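"""Table and network writers/readers used by the CLI.

All tabular output is TSV (tab-separated, header row, UTF-8, '.' decimal) or
JSON; simulator bond ledgers can additionally go out as two-column edge
lists or GraphML for network tools.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import pandas as pd

from .simulator import SimState

PathLike = Union[str, Path]


def rows_to_frame(rows: Iterable[Mapping[str, Any]]) -> pd.DataFrame:
    return pd.DataFrame(list(rows))


def write_tsv(rows: Iterable[Mapping[str, Any]], out: Optional[PathLike]) -> None:
    """Write rows as TSV to a path, or to stdout when ``out`` is None."""
    frame = rows_to_frame(rows)
    target = sys.stdout if out is None else out
    frame.to_csv(target, sep="\t", index=False)


def read_tsv(path: PathLike) -> pd.DataFrame:
    """Re-read a TSV emitted by this package (lossless at emitted precision)."""
    return pd.read_csv(path, sep="\t")


def write_json(payload: Any, out: Optional[PathLike]) -> None:
    text = json.dumps(payload, indent=2)
    if out is None:
        sys.stdout.write(text + "\n")
    else:
        Path(out).write_text(text + "\n", encoding="utf-8")


def write_edge_list(state: SimState, path: PathLike) -> None:
    """Bond ledger as two-column TSV (unit_id_a, unit_id_b), 0-based ids."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("unit_id_a\tunit_id_b\n")
        for u, v in state.bonds:
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path: PathLike) -> Sequence[tuple[int, int]]:
    frame = read_tsv(path)
    return list(zip(frame["unit_id_a"].astype(int), frame["unit_id_b"].astype(int)))


def write_graphml(state: SimState, path: PathLike) -> None:
    """Bond ledger as GraphML, including isolated (monomeric) units."""
    graph = nx.Graph()
    graph.add_nodes_from(range(state.config.N))
    graph.add_edges_from(state.bonds)
    nx.write_graphml(graph, path)
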
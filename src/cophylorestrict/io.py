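"""Readers and writers for the pipeline's file formats.

Trees travel as newick (internal-node labels read as bootstrap supports),
tables as TSV. Incidence input may contain counts; anything > 0 is coerced
to presence, since the pipeline treats occurrence data as presence/absence
throughout.
"""

from __future__ import annotations

import os
from typing import Sequence, Union

import dendropy
import numpy as np
import pandas as pd

from .model import (CladeRecord, HostTree, IncidenceMatrix, SampleTable,
                    SymbiontTree, ValidationError)


class NewickParseError(ValueError):
    """Malformed newick input (wraps the parser's line/column report)."""


def _parse_supports(tree: dendropy.Tree) -> None:
    """Interpret numeric internal-node labels as bootstrap supports.

    Supports on a 0-1 scale are rescaled x100 when every labelled value
    is <= 1, so thresholds can always be quoted on the 0-100 scale.
    """
    values = []
    for node in tree.preorder_internal_node_iter():
        sup = None
        if node.label is not None:
            try:
                sup = float(node.label)
            except ValueError:
                sup = None
        node.support = sup
        if sup is not None:
            values.append(sup)
    if values and max(values) <= 1.0:
        for node in tree.preorder_internal_node_iter():
            if node.support is not None:
                node.support = round(node.support * 100.0, 10)


def parse_newick(text: str, kind: str = "symbiont"):
    """Parse a newick string (same semantics as :func:`read_newick`)."""
    if kind not in ("symbiont", "host"):
        raise ValueError(f"kind must be 'symbiont' or 'host', got {kind!r}")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickParseError(str(exc)) from exc
    _parse_supports(tree)
    return (SymbiontTree if kind == "symbiont" else HostTree)(tree)


def read_newick(path: Union[str, os.PathLike], kind: str = "symbiont"):
    """Read a rooted newick tree.

    Parameters
    ----------
    path : str
        Newick file with branch lengths; internal-node labels, when
        numeric, are interpreted as bootstrap support values.
    kind : {'symbiont', 'host'}
        'symbiont' returns a :class:`SymbiontTree`; 'host' returns a
        :class:`HostTree` (validated ultrametric, branch lengths in Myr).
    """
    if kind not in ("symbiont", "host"):
        raise ValueError(f"kind must be 'symbiont' or 'host', got {kind!r}")
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # dendropy reports line/column in its message
        raise NewickParseError(f"{path}: {exc}") from exc
    _parse_supports(tree)
    cls = SymbiontTree if kind == "symbiont" else HostTree
    return cls(tree)


def write_newick(tree, path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_newick())


def read_incidence(path: Union[str, os.PathLike]) -> IncidenceMatrix:
    """Read an ASV x sample TSV (header = sample ids, first column = ASV ids).

    Entries may be counts; they are binarized as presence = value > 0.
    All-zero rows and non-numeric entries are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        numeric = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric incidence entry ({exc})")
    return IncidenceMatrix((numeric > 0).astype(np.int8))


def write_incidence(matrix: IncidenceMatrix, path: Union[str, os.PathLike]) -> None:
    matrix.df.to_csv(path, sep="\t", index_label="asv_id")


def read_metadata(path: Union[str, os.PathLike]) -> SampleTable:
    """Read the per-sample metadata TSV (see :class:`SampleTable` columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=["NA", ""])
    return SampleTable(df)


def write_metadata(samples: SampleTable, path: Union[str, os.PathLike]) -> None:
    out = samples.df.reset_index(drop=True).copy()
    for col in ("site", "enclosure"):
        out[col] = out[col].fillna("NA")
    out.to_csv(path, sep="\t", index=False)


def clade_frame(clades: Sequence[CladeRecord]) -> pd.DataFrame:
    """Tabulate clade records, one row per clade, sorted by clade_id."""
    prev_groups = sorted({g for c in clades for g in c.prevalence})
    rows = []
    for c in clades:
        row = {
            "clade_id": c.clade_id,
            "category": c.category,
            "host_species": c.host_species if c.host_species else "NA",
            "n_asvs": len(c.member_asvs),
            "support": c.support,
            "n_individuals": c.n_individuals,
            "member_asvs": ";".join(c.member_asvs),
        }
        for g in prev_groups:
            row[f"prev_{g}"] = c.prevalence.get(g, np.nan)
        rows.append(row)
    cols = ["clade_id", "category", "host_species", "n_asvs", "support",
            "n_individuals", "member_asvs"] + [f"prev_{g}" for g in prev_groups]
    frame = pd.DataFrame(rows, columns=cols)
    return frame.sort_values("clade_id", kind="stable").reset_index(drop=True)


def write_clade_table(clades: Sequence[CladeRecord],
                      path: Union[str, os.PathLike]) -> None:
    """Write the clade table as TSV with deterministic row order."""
    clade_frame(clades).to_csv(path, sep="\t", index=False, float_format="%.10g")
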
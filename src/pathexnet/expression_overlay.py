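"""Expression overlays: per-protein scores, ON/OFF/NA states, filtering.

The overlay answers one question per protein and cellular context: is the
protein's gene expressed there?  Three states are possible:

* ``ON``  — score strictly above the threshold (default 0.4),
* ``OFF`` — score at or below the threshold,
* ``NA``  — the protein is absent from the expression resource (e.g. not
  represented on the measurement platform), so no call can be made.

The strict inequality matters at the boundary: a score of exactly 0.4 is
OFF, a score of 0.41 is ON.

Scores come either from a precomputed gene-by-context table (barcode-style
fractions in [0, 1], or raw FPKM / EST values judged against an absolute,
user-supplied cutoff) or from :func:`barcode_scores`, a simplified
presence/absence caller: given each gene's unexpressed reference
distribution (mu, sigma), a gene is called expressed in a sample when its
z-score exceeds a cutoff (default 5), and the per-context score is the
fraction of that context's samples in which the gene is called expressed.
Choosing such cutoffs from raw data is not trivial, which is why both the
z-cutoff and the state threshold stay configurable.

Filtering keeps ON and NA nodes — a protein that cannot be measured is
not evidence of absence — and removes OFF nodes together with every
incident edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import OverlayError
from .id_mapping import MappingTable
from .network_builder import ProteinNetwork

__all__ = [
    "ExpressionResource",
    "StateAssignment",
    "FilterReport",
    "barcode_scores",
    "barcode_resource_from_samples",
    "load_expression",
    "assign_states",
    "filter_network",
    "compare_contexts",
]

RESOURCE_KINDS = ("barcode_fraction", "fpkm", "est_count", "custom")

DEFAULT_THRESHOLD = 0.4
DEFAULT_Z_CUTOFF = 5.0


@dataclass
class ExpressionResource:
    """A gene-or-accession × context score table with its threshold rule.

    ``barcode_fraction`` values are fractions in [0, 1] compared against a
    relative threshold; ``fpkm`` / ``est_count`` values are non-negative
    raw levels compared against an absolute ``threshold`` that the user
    must supply (no default is meaningful across platforms).
    """

    resource_kind: str
    values: pd.DataFrame  # rows: gene or accession ids; columns: contexts
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.resource_kind not in RESOURCE_KINDS:
            raise OverlayError(
                f"unknown resource kind {self.resource_kind!r}; expected one "
                f"of {RESOURCE_KINDS}"
            )
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if self.resource_kind == "barcode_fraction":
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise OverlayError(
                    "barcode_fraction scores must lie in [0, 1]"
                )
        elif self.resource_kind in ("fpkm", "est_count"):
            if finite.size and finite.min() < 0:
                raise OverlayError(
                    f"{self.resource_kind} values must be non-negative"
                )

    @property
    def contexts(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class StateAssignment:
    """ON/OFF/NA states (and the underlying scores, where available) for
    every node of one network in one context."""

    context: str
    states: dict[str, str]
    scores: dict[str, Optional[float]]
    threshold: float = DEFAULT_THRESHOLD

    def on_set(self) -> set[str]:
        return {a for a, s in self.states.items() if s == "ON"}

    def na_set(self) -> set[str]:
        return {a for a, s in self.states.items() if s == "NA"}

    def off_set(self) -> set[str]:
        return {a for a, s in self.states.items() if s == "OFF"}


@dataclass
class FilterReport:
    n_ON: int
    n_NA: int
    n_OFF_removed: int
    edges_kept: int
    edges_removed: int


def barcode_scores(
    expr_matrix: pd.DataFrame,
    reference: pd.DataFrame,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
) -> tuple[pd.Series, list[str]]:
    """Fraction-of-samples-expressed scores for one context.

    Parameters
    ----------
    expr_matrix:
        Genes in rows, samples (all from one context) in columns.
    reference:
        Per-gene unexpressed distribution; columns ``mu`` and ``sigma``
        (``sigma`` strictly positive).
    z_cutoff:
        A gene is called expressed in a sample iff
        ``(x - mu) / sigma > z_cutoff``.

    Returns the per-gene score series (values in [0, 1]) and the list of
    genes missing from the reference, for which no score is produced.
    """
    for col in ("mu", "sigma"):
        if col not in reference.columns:
            raise OverlayError(f"reference table lacks a {col!r} column")
    if (reference["sigma"] <= 0).any():
        bad = reference.index[reference["sigma"] <= 0].tolist()
        raise OverlayError(f"non-positive sigma for genes: {bad}")
    genes = expr_matrix.index
    missing = [g for g in genes if g not in reference.index]
    covered = [g for g in genes if g in reference.index]
    if not covered:
        return pd.Series(dtype=float), missing
    x = expr_matrix.loc[covered].to_numpy(dtype=float)
    mu = reference.loc[covered, "mu"].to_numpy(dtype=float)[:, None]
    sigma = reference.loc[covered, "sigma"].to_numpy(dtype=float)[:, None]
    expressed = (x - mu) / sigma > z_cutoff
    scores = pd.Series(expressed.mean(axis=1), index=covered, name="score")
    return scores, missing


def barcode_resource_from_samples(
    expr_matrix: pd.DataFrame,
    sample_contexts: pd.Series,
    reference: pd.DataFrame,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
) -> ExpressionResource:
    """Build a barcode-fraction resource from a gene × sample matrix and a
    sample → context manifest, scoring each context separately."""
    unknown = [s for s in expr_matrix.columns if s not in sample_contexts.index]
    if unknown:
        raise OverlayError(f"samples without a context: {unknown}")
    cols = {}
    for context in sorted(sample_contexts.unique()):
        samples = [
            s
            for s in expr_matrix.columns
            if sample_contexts[s] == context
        ]
        scores, _ = barcode_scores(expr_matrix[samples], reference, z_cutoff)
        cols[context] = scores
    table = pd.DataFrame(cols)
    return ExpressionResource("barcode_fraction", table)


def load_expression(
    path: Union[str, Path],
    kind: str = "barcode_fraction",
    threshold: Optional[float] = None,
) -> ExpressionResource:
    """Read a gene-or-accession × context score table (TSV, or CSV by
    ``.csv`` suffix; first column is the identifier)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionResource(kind, table, threshold)


def _invert_mapping(mapping: MappingTable) -> dict[str, set[str]]:
    inv: dict[str, set[str]] = {}
    for source_id, accs in mapping.pairs.items():
        for acc in accs:
            inv.setdefault(acc, set()).add(source_id)
    return inv


def assign_states(
    network: ProteinNetwork,
    resource: ExpressionResource,
    context: str,
    threshold: float = DEFAULT_THRESHOLD,
    mapping: Optional[MappingTable] = None,
    aggregate: str = "max",
) -> StateAssignment:
    """Assign one ON/OFF/NA state to every node of the network.

    The resource may be keyed directly by accession or by gene id; in the
    latter case an id-mapping table translates each node's accession to its
    gene rows.  When several rows match one accession the score is their
    maximum by default ("any evidence of expression"), or the mean with
    ``aggregate="mean"``.

    ON iff score strictly above the threshold; OFF iff at or below; NA iff
    the accession (and all its mapped gene ids) is absent from the table.
    For raw-level resources (fpkm / est_count) the resource's absolute
    threshold replaces the fractional one.
    """
    if context not in resource.values.columns:
        raise OverlayError(
            f"context {context!r} not in resource; available contexts: "
            + ", ".join(map(str, resource.contexts))
        )
    if resource.resource_kind in ("fpkm", "est_count"):
        if resource.threshold is None:
            raise OverlayError(
                f"{resource.resource_kind} resources need an absolute "
                "threshold (none supplied)"
            )
        effective_threshold = resource.threshold
    else:
        effective_threshold = threshold
        if resource.resource_kind == "barcode_fraction" and not (
            0.0 <= effective_threshold <= 1.0
        ):
            raise OverlayError(
                f"threshold {effective_threshold} outside [0, 1] for a "
                "barcode_fraction resource"
            )
    if aggregate not in ("max", "mean"):
        raise OverlayError(f"aggregate must be 'max' or 'mean', got {aggregate!r}")

    column = resource.values[context]
    inv = _invert_mapping(mapping) if mapping is not None else {}
    states: dict[str, str] = {}
    scores: dict[str, Optional[float]] = {}
    for acc in network.graph.nodes:
        keys = [acc] if acc in column.index else []
        keys += [g for g in sorted(inv.get(acc, ())) if g in column.index]
        vals = [float(column[k]) for k in keys if pd.notna(column[k])]
        if not vals:
            states[acc] = "NA"
            scores[acc] = None
            continue
        score = max(vals) if aggregate == "max" else float(np.mean(vals))
        scores[acc] = score
        states[acc] = "ON" if score > effective_threshold else "OFF"
    return StateAssignment(
        context=context,
        states=states,
        scores=scores,
        threshold=effective_threshold,
    )


def apply_assignment(
    network: ProteinNetwork, assignment: StateAssignment
) -> ProteinNetwork:
    """Write states and scores onto a copy of the network's node records."""
    net = network.copy()
    for acc in net.graph.nodes:
        if acc not in assignment.states:
            raise OverlayError(f"node {acc} has no assigned state")
        net.graph.nodes[acc]["state"] = assignment.states[acc]
        net.graph.nodes[acc]["score"] = assignment.scores.get(acc)
    return net


def filter_network(
    network: ProteinNetwork, assignment: StateAssignment
) -> tuple[ProteinNetwork, FilterReport]:
    """Reduce a network to its expression-specific subnetwork.

    ON and NA nodes are retained (NA is absence of evidence, not evidence
    of absence); OFF nodes are removed together with every incident edge.
    All node and edge attributes, including pathway provenance, survive.
    """
    missing = [a for a in network.graph.nodes if a not in assignment.states]
    if missing:
        raise OverlayError(
            "nodes without a state in the assignment: " + ", ".join(sorted(missing))
        )
    net = apply_assignment(network, assignment)
    off = {a for a in net.graph.nodes if assignment.states[a] == "OFF"}
    n_on = sum(1 for a in net.graph.nodes if assignment.states[a] == "ON")
    n_na = sum(1 for a in net.graph.nodes if assignment.states[a] == "NA")
    edges_before = net.n_edges
    net.graph.remove_nodes_from(off)
    report = FilterReport(
        n_ON=n_on,
        n_NA=n_na,
        n_OFF_removed=len(off),
        edges_kept=net.n_edges,
        edges_removed=edges_before - net.n_edges,
    )
    return net, report


def compare_contexts(
    network: ProteinNetwork, assignments: Sequence[StateAssignment]
) -> tuple[pd.DataFrame, list[str]]:
    """Side-by-side state table across contexts, plus the discordant genes
    (ON in at least one context and OFF in at least one other; NA never
    counts toward discordance)."""
    if len(assignments) < 2:
        raise OverlayError("need at least two assignments to compare")
    node_set = set(network.graph.nodes)
    for a in assignments:
        if set(a.states) != node_set:
            raise OverlayError(
                f"assignment for context {a.context!r} does not cover the "
                "network's node set"
            )
    table = pd.DataFrame(
        {a.context: pd.Series(a.states) for a in assignments}
    ).loc[sorted(node_set)]
    discordant = [
        acc
        for acc in table.index
        if "ON" in set(table.loc[acc]) and "OFF" in set(table.loc[acc])
    ]
    return table, discordant
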
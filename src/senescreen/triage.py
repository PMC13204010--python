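"""Interactor triage: multi-gene-set membership frequency, an
expression-response filter, term enrichment, and focal-term subnetworks.

The workflow mirrors a common prioritization pattern for
co-immunoprecipitation hit lists: each hit is cross-referenced against
several senescence/ageing annotation gene sets, hits present in at least
``k`` sets survive, and the survivors are further filtered by whether
they respond (log-ratio up, q-value significant) under a panel of
senescence-inducing stimuli.  Term over-representation uses the
one-sided Fisher exact test (hypergeometric tail) with
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)


def normalize_id(identifier: str) -> str:
    """Canonical form of a gene/protein symbol: stripped, uppercase.

    Symbols are treated as opaque; no alias or ortholog mapping is
    attempted.
    """
    return str(identifier).strip().upper()


def normalize_ids(identifiers: Iterable[str]) -> list[str]:
    """Canonicalize and de-duplicate, preserving first-seen order."""
    seen: dict[str, None] = {}
    for ident in identifiers:
        canon = normalize_id(ident)
        if canon:
            seen.setdefault(canon, None)
    return list(seen)


@dataclass
class AnnotationCollection:
    """Named gene sets (canonical identifiers) with free-text provenance."""

    sets: dict[str, frozenset[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
        self.sets = {name: frozenset(normalize_id(m) for m in members)
                     for name, members in self.sets.items()}

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def load_gene_sets(path: str | Path) -> AnnotationCollection:
    """Read gene sets from GMT (name, description, members...) or from a
    two-column CSV (set name, member identifier)."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    provenance: dict[str, str] = {}
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as handle:
            reader = csv.reader(handle)
            rows = [r for r in reader if r]
        if not rows:
            raise FormatError(f"{path}: empty gene-set file")
        start = 1 if rows[0] and rows[0][0].lower() in ("set", "set_name", "name") else 0
        for lineno, row in enumerate(rows[start:], start=start + 1):
            if len(row) < 2:
                raise FormatError(f"{path}: line {lineno}: need set,identifier")
            sets.setdefault(row[0].strip(), set()).add(normalize_id(row[1]))
    else:
        with open(path) as handle:
            lines = [ln.rstrip("\n") for ln in handle]
        if not any(ln.strip() for ln in lines):
            raise FormatError(f"{path}: empty gene-set file")
        for lineno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT record needs name, "
                    f"description and at least one member "
                    f"(got {len(fields)} fields)")
            name, description, *members = fields
            sets[name.strip()] = {normalize_id(m) for m in members if m.strip()}
            provenance[name.strip()] = description.strip()
    return AnnotationCollection({n: frozenset(s) for n, s in sets.items()},
                                provenance)


@dataclass
class MembershipMatrix:
    """Per-protein membership flags across the annotation sets."""

    flags: pd.DataFrame       # index: proteins; columns: set names; bool

    @property
    def proteins(self) -> list[str]:
        return list(self.flags.index)

    @property
    def set_names(self) -> list[str]:
        return list(self.flags.columns)

    @property
    def frequency(self) -> pd.Series:
        return self.flags.sum(axis=1).astype(int)


def membership_matrix(coip: Sequence[str],
                      collection: AnnotationCollection) -> MembershipMatrix:
    """Cross-reference a Co-IP hit list with every annotation set.

    Duplicate input identifiers (after canonicalization) are collapsed
    with a warning; row order follows first appearance in the input.
    """
    if not list(coip):
        raise ParameterError("the Co-IP identifier list is empty")
    canon = normalize_ids(coip)
    n_dupes = len([c for c in coip if normalize_id(c)]) - len(canon)
    if n_dupes > 0:
        logger.warning("collapsed %d duplicate Co-IP identifiers", n_dupes)
    data = {name: [p in members for p in canon]
            for name, members in collection.sets.items()}
    flags = pd.DataFrame(data, index=pd.Index(canon, name="protein"),
                         dtype=bool)
    return MembershipMatrix(flags)


def frequency_filter(matrix: MembershipMatrix, k: int) -> pd.DataFrame:
    """Flag proteins that belong to at least ``k`` annotation sets.

    Returns the candidate table: one row per protein with its
    set-membership frequency, the member sets, and ``passed_frequency``;
    sorted by frequency descending then identifier ascending.
    """
    n_sets = len(matrix.set_names)
    if not 1 <= k <= n_sets:
        raise ParameterError(f"k must be in [1, {n_sets}], got {k}")
    freq = matrix.frequency
    member_sets = matrix.flags.apply(
        lambda row: ";".join(c for c in matrix.set_names if row[c]), axis=1)
    table = pd.DataFrame({
        "protein": matrix.proteins,
        "frequency": freq.values,
        "member_sets": member_sets.values,
        "passed_frequency": (freq >= k).values,
    })
    table = table.sort_values(["frequency", "protein"],
                              ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    return table


def expression_filter(candidates: pd.DataFrame,
                      table: pd.DataFrame,
                      mode: str = "all",
                      q_max: float = 0.05,
                      lr_min: float = 0.0) -> pd.DataFrame:
    """Flag frequency-passing candidates that respond under the stimuli.

    A protein responds in a stimulus when ``logRatio > lr_min`` and
    ``qValue <= q_max``.  ``mode="all"`` requires a response in every
    stimulus present in the expression table; ``mode="any"`` in at least
    one.  Proteins absent from the table fail with a logged warning.
    ``passed_expression`` is left undefined (NA) for proteins that did
    not pass the frequency filter.
    """
    if mode not in ("all", "any"):
        raise ParameterError(f"mode must be 'all' or 'any', got {mode!r}")
    if not 0.0 < q_max <= 1.0:
        raise ParameterError("q_max must be in (0, 1]")
    expr = table.copy()
    expr["protein"] = expr["protein"].map(normalize_id)
    grouped = expr.groupby("protein")

    out = candidates.copy()
    flags: list[object] = []
    for _, row in out.iterrows():
        if not row["passed_frequency"]:
            flags.append(pd.NA)
            continue
        protein = row["protein"]
        if protein not in grouped.groups:
            logger.warning("protein %s absent from the expression table; "
                           "fails the expression filter", protein)
            flags.append(False)
            continue
        sub = grouped.get_group(protein)
        hit = (sub["logRatio"] > lr_min) & (sub["qValue"] <= q_max)
        flags.append(bool(hit.all()) if mode == "all" else bool(hit.any()))
    out["passed_expression"] = pd.array(flags, dtype="boolean")
    return out


def enrich(list_ids: Sequence[str],
           background: Sequence[str],
           terms: AnnotationCollection,
           top_n: int | None = 15) -> pd.DataFrame:
    """Term over-representation of ``list_ids`` against ``background``.

    Per term, the one-sided Fisher exact p-value toward enrichment is
    the hypergeometric upper tail P[X >= hits] for the 2x2 table
    (list∩term, list∖term, (background∖list)∩term, remainder);
    Benjamini-Hochberg FDR is applied over all tested terms.  The result
    is ordered by FDR ascending and truncated to ``top_n`` rows
    (``None`` keeps every term).  An infinite odds ratio (empty
    off-diagonal) is reported as ``inf``.
    """
    lst = set(normalize_ids(list_ids))
    bg = set(normalize_ids(background))
    stray = lst - bg
    if stray:
        logger.warning("dropped %d list identifiers absent from the "
                       "background", len(stray))
        lst -= stray
    if not lst or not bg:
        raise ParameterError("need a non-empty list and background")
    M = len(bg)
    n_list = len(lst)
    rows = []
    for name, members in terms.sets.items():
        in_bg = members & bg
        if not in_bg:
            logger.warning("term %s has no background overlap; skipped", name)
            continue
        K = len(in_bg)
        a = len(lst & in_bg)              # list ∩ term
        b = n_list - a                    # list ∖ term
        c = K - a                         # (bg ∖ list) ∩ term
        d = (M - n_list) - c
        p = float(hypergeom.sf(a - 1, M, K, n_list))
        odds = np.inf if b * c == 0 and a * d > 0 else (
            np.nan if b * c == 0 else (a * d) / (b * c))
        rows.append((name, a, n_list, K, M, odds, min(p, 1.0)))
    if not rows:
        raise ParameterError("no term overlaps the background")
    result = pd.DataFrame(rows, columns=[
        "term", "hits_in_list", "list_size", "hits_in_background",
        "background_size", "odds_ratio", "p_value"])
    result["fdr"] = multipletests(result["p_value"], method="fdr_bh")[1]
    result["neg_log10_fdr"] = -np.log10(result["fdr"])
    result = result.sort_values(["fdr", "p_value", "term"],
                                kind="mergesort").reset_index(drop=True)
    if top_n is not None:
        result = result.head(top_n).reset_index(drop=True)
    return result


def plot_enrichment(result: pd.DataFrame, path: str | Path,
                    top_n: int = 15) -> None:
    """Horizontal bar chart of -log10(FDR) for the top enriched terms."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = result.head(top_n).iloc[::-1]
    fig, ax = plt.subplots(figsize=(8, 0.4 * max(len(shown), 4) + 1))
    ax.barh(shown["term"], shown["neg_log10_fdr"], color="#4c72b0")
    ax.set_xlabel("$-\\log_{10}$(FDR)")
    ax.set_title("Enriched terms")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ego_subnetwork(edges: Iterable[tuple[str, str]],
                   focal: str,
                   depth: int = 1) -> tuple[set[str], list[tuple[str, str]]]:
    """Nodes within graph distance ``depth`` of the focal term, plus the
    induced edges (a k-nearest-neighbour style neighbourhood around a
    focal annotation node)."""
    if depth < 0:
        raise ParameterError("depth must be >= 0")
    graph = nx.Graph()
    graph.add_edges_from(edges)
    if focal not in graph:
        raise LookupError(f"focal node {focal!r} not present in the edge list")
    ego = nx.ego_graph(graph, focal, radius=depth)
    return set(ego.nodes), [tuple(sorted(e)) for e in ego.edges]
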
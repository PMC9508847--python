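"""Directional gene-set enrichment and diagnostic-set derivation.

Enrichment is an exact upper-tail hypergeometric test, run separately on
each inhibitor's significantly beneficial and significantly deleterious
gene-deletion lists, with p <= 1e-4 taken as enriched (no multiplicity
correction: functional categories overlap heavily and FDR methods
over-correct in that regime). Diagnostic gene sets (Lee_Positive /
Lee_Negative per response-signature compound set) are derived from a
reference compendium of compound x gene fitness z-scores, and enrichments
are assembled into a signed -log10(p) matrix (negative = deleterious-list)
with hierarchical clustering.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom

from . import io as cgio
from .diffit import FitnessTable
from .synthpool import ReferenceCompendium

UNIVERSE_MODES = ("tested", "all", "union")


def hypergeom_enrich(gene_list: set[str], gene_set: set[str],
                     universe: set[str]) -> tuple[float, int]:
    """Exact upper-tail hypergeometric p-value for the overlap of a tested
    gene list with a gene set inside a finite universe.

    Returns (p, overlap) where p = P(X >= overlap) with population
    |universe|, successes |gene_set|, draws |gene_list|.
    """
    if not universe:
        raise ValueError("empty universe")
    gene_list = set(gene_list) & universe
    gene_set = set(gene_set) & universe
    k = len(gene_list & gene_set)
    p = float(hypergeom.sf(k - 1, len(universe), len(gene_set), len(gene_list)))
    return min(p, 1.0), k


def enrich_all(fitness: FitnessTable, sets: "OrderedDict[str, list[str]]",
               universe_mode: str = "tested", p_cutoff: float = 1e-4,
               min_size: int = 3) -> pd.DataFrame:
    """Directional enrichment of every gene set for every inhibitor.

    For each inhibitor two lists are tested separately: genes whose deletion
    is significantly beneficial and significantly deleterious. The universe
    is the genes tested for that inhibitor (default), all genes, or the
    significant union. Sets smaller than ``min_size`` after mapping to the
    universe are skipped (flagged in ``attrs['skipped_sets']``).
    """
    if universe_mode not in UNIVERSE_MODES:
        raise ValueError(f"unknown universe_mode {universe_mode!r}")
    t = fitness.table
    all_genes = set(t["gene"].unique())
    union_genes = set(fitness.significant_union)
    rows = []
    skipped: set[str] = set()
    for inh, part in t.groupby("inhibitor"):
        if universe_mode == "tested":
            universe = set(part.loc[part["p_value"].notna(), "gene"])
        elif universe_mode == "all":
            universe = all_genes
        else:
            universe = union_genes
        for direction in ("beneficial", "deleterious"):
            lst = set(part.loc[part["direction"] == direction, "gene"])
            lst &= universe
            for name, members in sets.items():
                mset = set(members) & universe
                if len(mset) < min_size:
                    skipped.add(name)
                    continue
                if not lst:
                    p, k = 1.0, 0
                else:
                    p, k = hypergeom_enrich(lst, mset, universe)
                rows.append({"inhibitor": inh, "direction": direction,
                             "category": name, "overlap": k,
                             "list_size": len(lst), "set_size": len(mset),
                             "universe_size": len(universe), "p_value": p,
                             "enriched": p <= p_cutoff,
                             "empty_list": len(lst) == 0})
    out = pd.DataFrame(rows)
    out.attrs["p_cutoff"] = p_cutoff
    out.attrs["universe_mode"] = universe_mode
    out.attrs["skipped_sets"] = sorted(skipped)
    return out


def derive_diagnostic_sets(compendium: ReferenceCompendium,
                           z_threshold: float = 3.09,
                           assoc_cutoff: float = 1e-3
                           ) -> "OrderedDict[str, list[str]]":
    """Derive Lee_Positive / Lee_Negative diagnostic gene sets.

    A gene joins ``Lee_Positive(S)`` when its positive scores with
    |z| > ``z_threshold`` are concentrated in signature set S more than
    expected by chance: upper-tail hypergeometric with population = all
    reference compounds, successes = |S|, draws = the gene's significant
    compounds of that sign, overlap = those inside S; association requires
    p <= ``assoc_cutoff``. Negative scores are treated symmetrically.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be > 0")
    z = compendium.z
    set_map = compendium.set_map
    n_comp = z.shape[0]
    set_names = sorted(set_map.unique())
    members = {s: set_map.index[set_map == s] for s in set_names}
    for s, m in members.items():
        if len(m) < 2:
            raise ValueError(f"signature set {s} has < 2 compounds")
    out: OrderedDict[str, list[str]] = OrderedDict()
    for s in set_names:
        out[f"Lee_Positive({s})"] = []
        out[f"Lee_Negative({s})"] = []
    zv = z.to_numpy()
    for gi, gene in enumerate(z.columns):
        col = zv[:, gi]
        for dname, mask in (("Positive", col > z_threshold),
                            ("Negative", col < -z_threshold)):
            draws = int(mask.sum())
            if draws == 0:
                continue
            for s in set_names:
                in_set = set_map.to_numpy() == s
                k = int((mask & in_set).sum())
                if k == 0:
                    continue
                p = float(hypergeom.sf(k - 1, n_comp, int(in_set.sum()), draws))
                if p <= assoc_cutoff:
                    out[f"Lee_{dname}({s})"].append(gene)
    for key in out:
        out[key] = sorted(out[key])
    return out


@dataclass
class EnrichmentMatrix:
    """Signed -log10(p) enrichment scores: category x inhibitor; positive =
    beneficial-list enrichment, negative = deleterious-list."""

    scores: pd.DataFrame
    p_cutoff: float
    ties: list[tuple[str, str]]
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_newick: str | None
    col_newick: str | None


def signed_matrix_and_cluster(enrichments: pd.DataFrame,
                              p_cutoff: float | None = None
                              ) -> EnrichmentMatrix:
    """Assemble the signed enrichment matrix and cluster it.

    Cells with p <= cutoff on either list are retained as
    sign * -log10(p); when a category passes on both lists of one inhibitor
    the smaller p wins (exact tie -> 0, flagged). Rows (categories) and
    columns are clustered by average linkage on Euclidean distance.
    """
    if p_cutoff is None:
        p_cutoff = float(enrichments.attrs.get("p_cutoff", 1e-4))
    hits = enrichments[enrichments["p_value"] <= p_cutoff]
    if hits.empty:
        return EnrichmentMatrix(scores=pd.DataFrame(), p_cutoff=p_cutoff,
                                ties=[], row_linkage=None, col_linkage=None,
                                row_newick=None, col_newick=None)
    cats = sorted(hits["category"].unique())
    inhs = sorted(hits["inhibitor"].unique())
    scores = pd.DataFrame(0.0, index=pd.Index(cats, name="category"),
                          columns=inhs)
    ties = []
    for (cat, inh), grp in hits.groupby(["category", "inhibitor"]):
        by_dir = grp.set_index("direction")["p_value"]
        if len(by_dir) == 2:
            pb, pd_ = by_dir.get("beneficial", 1.0), by_dir.get("deleterious", 1.0)
            if pb == pd_:
                ties.append((cat, inh))
                continue
            direction, p = (("beneficial", pb) if pb < pd_
                            else ("deleterious", pd_))
        else:
            direction = by_dir.index[0]
            p = float(by_dir.iloc[0])
        sign = 1.0 if direction == "beneficial" else -1.0
        scores.at[cat, inh] = sign * -np.log10(max(p, 1e-300))

    row_linkage = col_linkage = None
    row_newick = col_newick = None
    if len(cats) >= 2:
        row_linkage = average(pdist(scores.to_numpy(), metric="euclidean"))
        order = [cats[i] for i in leaves_list(row_linkage)]
        row_newick = cgio.linkage_to_newick(row_linkage, cats)
        scores = scores.loc[order]
    if len(inhs) >= 2:
        col_linkage = average(pdist(scores.to_numpy().T, metric="euclidean"))
        col_newick = cgio.linkage_to_newick(col_linkage, inhs)
        corder = [inhs[i] for i in leaves_list(col_linkage)]
        scores = scores[corder]
    return EnrichmentMatrix(scores=scores, p_cutoff=p_cutoff, ties=ties,
                            row_linkage=row_linkage, col_linkage=col_linkage,
                            row_newick=row_newick, col_newick=col_newick)
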
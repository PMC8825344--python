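"""Per-module GO term over-representation analysis.

One-sided Fisher's exact test of each GO term's frequency in a module
against the remaining genes of the (variance-filtered) universe, with
Benjamini-Hochberg control across the terms tested within the module.
Annotation is treated as flat gene -> term sets; no ontology-graph
propagation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .modules import GeneModule, ModulePartition

__all__ = ["GOAnnotation", "EnrichmentResult", "fisher_enrichment", "stage_enrichment_table"]


@dataclass
class GOAnnotation:
    """Flat gene -> GO term mapping with term names and ontologies."""

    gene_to_terms: dict[str, set[str]]
    term_meta: pd.DataFrame  # columns: term_id, name, ontology

    def __post_init__(self) -> None:
        if not {"term_id", "name", "ontology"} <= set(self.term_meta.columns):
            raise ValueError("term_meta needs columns term_id, name, ontology")
        bad = set(self.term_meta["ontology"]) - {"BP", "MF", "CC"}
        if bad:
            raise ValueError(f"unknown ontology values: {sorted(bad)}")
        known = set(self.term_meta["term_id"])
        used = set().union(*self.gene_to_terms.values()) if self.gene_to_terms else set()
        missing = used - known
        if missing:
            raise ValueError(f"terms without metadata: {sorted(missing)[:5]}")

    def meta_of(self, term_id: str) -> tuple[str, str]:
        row = self.term_meta.loc[self.term_meta["term_id"] == term_id].iloc[0]
        return str(row["name"]), str(row["ontology"])


@dataclass
class EnrichmentResult:
    module_label: str
    term_id: str
    name: str
    ontology: str
    a: int  # in module, with term
    b: int  # in module, without term
    c: int  # background, with term
    d: int  # background, without term
    p_value: float
    fdr: float
    enriched: bool


def fisher_enrichment(
    module: GeneModule | list[str],
    universe: list[str] | set[str],
    annotation: GOAnnotation,
    alpha: float = 0.05,
    correction: str = "bh",
) -> list[EnrichmentResult]:
    """One-sided over-representation test for every term seen in the module.

    Genes without annotation count as term-absent. Terms with zero
    in-module occurrences are not tested. ``correction`` is "bh"
    (Benjamini-Hochberg within the module) or "none".
    """
    if correction not in ("bh", "none"):
        raise ValueError("correction must be 'bh' or 'none'")
    if isinstance(module, GeneModule):
        label, module_genes = module.label, list(module.gene_ids)
    else:
        label, module_genes = "module", list(module)
    universe = set(universe)
    if not module_genes or not universe:
        raise ValueError("module and universe must be nonempty")
    if not set(module_genes) <= universe:
        raise ValueError("module genes must be a subset of the universe")
    module_set = set(module_genes)
    n_mod = len(module_set)
    n_uni = len(universe)

    term_in_module: dict[str, int] = {}
    term_in_universe: dict[str, int] = {}
    for g in universe:
        for t in annotation.gene_to_terms.get(g, ()):  # unannotated -> absent
            term_in_universe[t] = term_in_universe.get(t, 0) + 1
            if g in module_set:
                term_in_module[t] = term_in_module.get(t, 0) + 1

    rows = []
    for t in sorted(term_in_module):
        a = term_in_module[t]
        k = term_in_universe[t]
        b = n_mod - a
        c = k - a
        d = (n_uni - n_mod) - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((t, a, b, c, d, float(p)))
    if not rows:
        return []
    pvals = [r[5] for r in rows]
    if correction == "bh":
        _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        fdrs = pvals
    results = []
    for (t, a, b, c, d, p), q in zip(rows, fdrs):
        name, ontology = annotation.meta_of(t)
        results.append(
            EnrichmentResult(
                module_label=label,
                term_id=t,
                name=name,
                ontology=ontology,
                a=a,
                b=b,
                c=c,
                d=d,
                p_value=p,
                fdr=float(q),
                enriched=bool(q <= alpha),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def stage_enrichment_table(
    partition: ModulePartition,
    annotation: GOAnnotation,
    universe: list[str] | set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Stage-specific modules x ontology table of enriched term names.

    One row per stage-specific module (ordered by peak day), columns for
    the module label, gene count, stage and the BP/MF/CC enriched terms;
    cells with no enriched terms read "Not detected".
    """
    if universe is None:
        universe = set()
        for m in partition.modules:
            universe |= set(m.gene_ids)
        universe |= set(partition.unassigned_gene_ids)
    rows = []
    mods = sorted(
        partition.stage_specific(),
        key=lambda m: (m.peak_day if m.peak_day is not None else 0.0, m.label),
    )
    for m in mods:
        results = fisher_enrichment(m, universe, annotation, alpha=alpha)
        row = {
            "module": m.label,
            "n_genes": m.size,
            "stage": m.stage,
        }
        for ont in ("BP", "MF", "CC"):
            names = sorted(
                {r.name for r in results if r.enriched and r.ontology == ont}
            )
            row[ont] = "; ".join(names) if names else "Not detected"
        rows.append(row)
    return pd.DataFrame(rows, columns=["module", "n_genes", "stage", "BP", "MF", "CC"])
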
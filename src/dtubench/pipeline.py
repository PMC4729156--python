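"""End-to-end experiment orchestration.

One *experiment* is a simulated two-condition dataset; one *arm* is a
(counting variant x catalog) analysis of that dataset: construct the
counting bins from a (possibly prefiltered or degraded) catalog, count
the simulated fragments, run the bin-vs-rest test, and label the
gene-level results against the truth.  The CLI wraps these stages with
plain-file handoffs; tests and the acceptance script call them in
memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation as anno
from . import counting, inference, simulate
from .annotation import Annotation, BinSet
from .counting import CountMatrix
from .simulate import SimParams

logger = logging.getLogger(__name__)

#: Counting variants: bin construction + counting paradigm.
VARIANTS = (
    "flat_aggregate",     # disjoint bins, overlapping genes -> complexes
    "flat_noaggreg",      # disjoint bins, same-strand overlap excluded
    "flat_bothstrands",   # disjoint bins, overlap on either strand excluded
    "exon",               # original exons, multi-assignment
    "junction",           # junction-spanning fragments only
    "transcript_em",      # isoform bins via equivalence-class EM
)

_FLAT_MODE = {
    "flat_aggregate": "aggregate",
    "flat_noaggreg": "exclude_same_strand",
    "flat_bothstrands": "exclude_both_strands",
}


@dataclass
class SimulatedExperiment:
    params: SimParams
    ann: Annotation
    model: simulate.ExpressionModel
    truth: pd.DataFrame
    sample_ids: list[str]
    conditions: np.ndarray
    expressions: list[simulate.SampleExpression]
    fragments: list[simulate.Fragment]
    blocks: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.blocks is None:
            self.blocks = counting.fragment_block_table(self.fragments)


def simulate_experiment(params: SimParams) -> SimulatedExperiment:
    """Simulate annotation, expression, truth, and all samples' fragments."""
    ann = simulate.generate_annotation(params)
    model = simulate.build_expression_model(ann, params)
    truth = simulate.select_dtu_genes(model, params)
    model = simulate.apply_dtu_swap(model, truth)
    nrep = params.n_replicates_per_condition
    sample_ids = [f"s{i + 1:02d}" for i in range(2 * nrep)]
    conditions = np.array([1] * nrep + [2] * nrep)
    expressions = []
    fragments: list[simulate.Fragment] = []
    for sid, cond in zip(sample_ids, conditions):
        expr = simulate.simulate_sample_expression(model, int(cond), sid, params)
        expressions.append(expr)
        fragments.extend(simulate.simulate_fragments(ann, expr, params))
    return SimulatedExperiment(
        params=params, ann=ann, model=model, truth=truth,
        sample_ids=sample_ids, conditions=conditions,
        expressions=expressions, fragments=fragments,
    )


def build_binset(ann: Annotation, variant: str) -> BinSet:
    if variant in _FLAT_MODE:
        return anno.flatten(ann, _FLAT_MODE[variant])
    if variant == "exon":
        return anno.exon_bins(ann)
    if variant == "junction":
        return anno.junction_set(ann)
    if variant == "transcript_em":
        return anno.transcript_bins(ann)
    raise ValueError(f"unknown counting variant {variant!r}")


def count_arm(
    exp: SimulatedExperiment, variant: str, catalog: Annotation | None = None
) -> CountMatrix:
    """Count the experiment's fragments under one variant and catalog.

    ``catalog`` defaults to the simulation's own annotation; pass a
    prefiltered or degraded catalog to emulate analysis with an edited
    reference.
    """
    catalog = exp.ann if catalog is None else catalog
    if variant == "transcript_em":
        eff = {
            t.transcript_id: simulate.effective_length(
                t.length, exp.params.fragment_length_mean
            )
            for t in catalog.transcripts().values()
        }
        return counting.transcript_count_matrix(
            exp.fragments, catalog, eff, samples=exp.sample_ids
        )
    binset = build_binset(catalog, variant)
    if variant == "junction":
        return counting.count_junctions(exp.blocks, binset)
    return counting.count_flat_or_exon(exp.blocks, binset)


def run_arm(
    exp: SimulatedExperiment,
    variant: str,
    catalog: Annotation | None = None,
    min_mean: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count + test one arm; returns (gene table, bin table)."""
    cm = count_arm(exp, variant, catalog)
    return inference.run_dtu_test(cm, exp.conditions, min_mean=min_mean)


def prefiltered_catalog(
    exp: SimulatedExperiment, threshold: float, mode: str = "true_condition"
) -> Annotation:
    """The experiment's catalog after isoform prefiltering."""
    if threshold == 0:
        return exp.ann
    if mode == "true_condition":
        ab = simulate.true_abundance_table(exp.model)
    else:
        ab = simulate.sample_abundance_table(exp.expressions)
    return anno.prefilter_isoforms(exp.ann, ab, threshold, mode=mode)
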
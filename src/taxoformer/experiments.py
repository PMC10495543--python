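"""Desk-scale end-to-end experiments: simulate, train, evaluate.

These helpers wire the synthetic generators, the estimator and the metrics
into one reproducible parameter-recovery experiment: simulate a small
genus/species taxonomy, train a classifier on coverage-balanced reads with
sequencing errors, and measure held-out read-level recall and the L2
distance between the inferred and true abundance profiles.  The test suite
and the acceptance script both run through this module.

The default problem — 3 genera x 3 species, 20 kb genomes, 15% between-genus
and 3% within-genus divergence, ~30,000 150 bp training reads with 1%
substitution error — is small enough for a CPU yet hard enough that a linear
model does not solve it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .estimator import TransformerReadClassifier
from .inference import abundance_profile
from .metrics import MetricsReport, l2_distance, precision_recall
from .synthetic import SimTaxonomy, generate_balanced_set, simulate_taxonomy


@dataclass
class ExperimentResult:
    """Metrics of one end-to-end parameter-recovery run."""

    species_recall: float
    species_precision: float
    genus_recall: float
    genus_precision: float
    profile_l2: float
    n_train_reads: int
    n_eval_reads: int
    steps_run: int
    best_val_loss: float
    estimator: TransformerReadClassifier = field(repr=False)
    genus_report: MetricsReport = field(repr=False)
    species_report: MetricsReport = field(repr=False)


def make_default_taxonomy(seed: int = 0) -> SimTaxonomy:
    """3 genera x 3 species, 20 kb genomes, d_between 0.15 / d_within 0.03."""
    return simulate_taxonomy(
        n_genera=3, species_per_genus=3, genome_length=20_000,
        d_between=0.15, d_within=0.03, seed=seed,
    )


def make_read_sets(
    taxonomy: SimTaxonomy,
    f_train: int = 25,
    f_eval: int = 2,
    err_rate: float = 0.01,
    seed: int = 0,
):
    """Coverage-balanced train and held-out read sets with disjoint ids/seeds.

    With nine 20 kb genomes, f_train=25 yields ~30,000 150 bp training reads;
    f_eval=2 gives a balanced held-out set of ~2,400 reads.
    """
    train_reads, train_manifest = generate_balanced_set(
        taxonomy, f_train, err_rate=err_rate, seed=seed, id_namespace="train",
    )
    eval_reads, eval_manifest = generate_balanced_set(
        taxonomy, f_eval, err_rate=err_rate, seed=seed + 104729, id_namespace="eval",
    )
    return train_reads, train_manifest, eval_reads, eval_manifest


def species_to_genus(taxonomy: SimTaxonomy) -> Dict[str, str]:
    return dict(taxonomy.species)


def evaluate_on_reads(
    est: TransformerReadClassifier,
    eval_reads,
    taxonomy: SimTaxonomy,
    threshold: float = 0.5,
) -> Tuple[MetricsReport, MetricsReport, float]:
    """Species/genus read-level metrics and abundance-profile L2 distance.

    For a single-level (species) model the genus call is the predicted
    species' parent genus; multi-level models use their genus head directly.
    The profile L2 compares inferred species fractions with the true (here
    balanced) composition of the held-out set.
    """
    s2g = species_to_genus(taxonomy)
    preds = list(est.classify(eval_reads, threshold=threshold))
    species_level = est.level_names_[-1]
    genus_level = est.level_names_[0] if est.n_levels_ > 1 else None

    species_pred, genus_pred = {}, {}
    for p in preds:
        sp = p.labels[species_level]
        species_pred[p.read_id] = sp
        if genus_level is not None:
            genus_pred[p.read_id] = p.labels[genus_level]
        else:
            genus_pred[p.read_id] = s2g.get(sp, sp)
    species_truth = {r.id: r.truth_labels["species"] for r in eval_reads}
    genus_truth = {r.id: r.truth_labels["genus"] for r in eval_reads}
    species_report = precision_recall(species_pred, species_truth)
    genus_report = precision_recall(genus_pred, genus_truth)

    species_ids = [sid for sid, _ in taxonomy.species]
    inferred = abundance_profile(preds, species_ids, level=species_level)
    truth_counts = {sid: 0 for sid in species_ids}
    for r in eval_reads:
        truth_counts[r.truth_labels["species"]] += 1
    total = sum(truth_counts.values())
    truth_profile = {sid: c / total for sid, c in truth_counts.items()}
    l2 = l2_distance(inferred.fractions, truth_profile)
    return species_report, genus_report, l2


def run_parameter_recovery(
    seed: int = 0,
    multilevel: bool = False,
    max_steps: int = 3000,
    threshold: float = 0.5,
    f_train: int = 25,
    f_eval: int = 2,
    err_rate: float = 0.01,
    **estimator_overrides,
) -> ExperimentResult:
    """Full pipeline: simulate, train (species or genus+species), evaluate.

    The model configuration is the desk-scale profile: Vocab k=6, d_model 32,
    1 encoder block, 4 heads, d_ff 256, mean reduction, batch 64, lr 2e-3,
    at most ``max_steps`` optimizer steps with early stopping.
    """
    taxonomy = make_default_taxonomy(seed=seed)
    train_reads, train_manifest, eval_reads, _ = make_read_sets(
        taxonomy, f_train=f_train, f_eval=f_eval, err_rate=err_rate, seed=seed,
    )
    X = [r.sequence for r in train_reads]
    if multilevel:
        y = train_manifest[["genus_id", "species_id"]].to_numpy()
    else:
        y = train_manifest["species_id"].to_numpy()
    params = dict(
        scheme="vocab", k=6, d_model=32, n_blocks=1, h=4, d_ff=256,
        reduction="mean", dropout=0.0, lr=2e-3, batch_size=64,
        max_steps=max_steps, patience=500, val_interval=100,
        val_fraction=0.1, random_state=seed,
    )
    params.update(estimator_overrides)
    est = TransformerReadClassifier(**params)
    est.fit(X, y)
    if multilevel:
        est.level_names_ = ["genus", "species"]
    species_report, genus_report, l2 = evaluate_on_reads(
        est, eval_reads, taxonomy, threshold=threshold
    )
    return ExperimentResult(
        species_recall=species_report.recall,
        species_precision=species_report.precision,
        genus_recall=genus_report.recall,
        genus_precision=genus_report.precision,
        profile_l2=l2,
        n_train_reads=len(train_reads),
        n_eval_reads=len(eval_reads),
        steps_run=est.train_state_.step,
        best_val_loss=est.train_state_.best_val_loss,
        estimator=est,
        genus_report=genus_report,
        species_report=species_report,
    )
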
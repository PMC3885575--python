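"""End-to-end orchestration: dataset → per-enzyme models → evaluation.

Ties the modules together the way the staged workflow runs them: assemble a
superfamily dataset, build each roster enzyme's sites/PSSM/schema from its
training alignment, train the forest and the baseline tree, extract rf-SDRs,
and evaluate test queries with MTTSI stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotation import assemble_sites, build_pssm, column_entropy, select_csrs, stack_to_reference
from .dataset import SuperfamilyDataset, build_superfamily_dataset
from .evaluation import PredictionResult, bin_results, compute_mttsi, macro_average
from .io import AnnotationRow, ProfileMatrix, SequenceRecord, blosum62
from .models import (
    EnzymeModelSpec,
    EnzymePredictor,
    extract_rf_sdrs,
    rank_importance,
    train_forest,
    train_simple,
)
from .scoring import build_attribute_vector, build_schema, top_hit_score

logger = logging.getLogger(__name__)

__all__ = ["SuperfamilyModels", "train_superfamily", "evaluate_superfamily"]


@dataclass
class SuperfamilyModels:
    """Trained per-enzyme predictors of one superfamily."""

    dataset: SuperfamilyDataset
    predictors: dict[str, EnzymePredictor] = field(default_factory=dict)
    seed: Optional[int] = None

    @property
    def roster(self) -> list[str]:
        return sorted(self.predictors)


def _ec_seed(base: Optional[int], index: int) -> Optional[int]:
    if base is None:
        return None
    return (base * 1009 + index) % (2**31)


def train_superfamily(
    dataset: SuperfamilyDataset,
    annotations: Sequence[AnnotationRow],
    seed: Optional[int] = None,
    esst_profiles: Optional[Mapping[str, ProfileMatrix]] = None,
    n_estimators: int = 500,
    mtry: Optional[int] = None,
    csr_fraction: float = 0.10,
) -> SuperfamilyModels:
    """Train one binary predictor per roster enzyme.

    For each enzyme: the training positives are stacked onto the
    representative to give the training alignment; conservation entropy
    yields the CSR set on top of the annotated ASR/LBR positions; the PSSM
    is built from the same alignment; and the forest is trained on the
    positives versus all other enzymes' training sequences.
    """
    matrix = blosum62()
    esst_profiles = esst_profiles or {}
    models = SuperfamilyModels(dataset=dataset, seed=seed)
    for index, ec in enumerate(sorted(dataset.roster)):
        group = dataset.group(ec)
        rep = group.representative
        positives = dataset.training_members(ec)
        negatives = dataset.negatives(ec, side="train")
        msa = stack_to_reference(positives, rep, matrix=matrix)
        profile = column_entropy(msa)
        raw_sites = assemble_sites(
            [row for row in annotations if row.ec == ec],
            representative_length=len(rep.sequence),
        )
        sites = select_csrs(profile, raw_sites, fraction=csr_fraction)
        pssm = build_pssm(msa, matrix)
        esst = esst_profiles.get(ec)
        schemes = ("blosum62", "pssm", "esst") if esst is not None else ("blosum62", "pssm")
        schema = build_schema(sorted(sites.all_positions), matrices=schemes)
        spec = EnzymeModelSpec(
            ec=ec,
            representative=rep,
            sites=sites,
            schema=schema,
            pssm=pssm,
            training_positives=positives,
            matrix=matrix,
            esst=esst,
        )
        vectors, labels = [], []
        for record in positives + negatives:
            vectors.append(build_attribute_vector(record, spec, mode="training"))
            labels.append(1 if record.ec == ec else 0)
        ec_seed = _ec_seed(seed, index)
        forest = train_forest(vectors, labels, n_estimators=n_estimators, mtry=mtry, seed=ec_seed)
        blast_col = [v.values[0] for v in vectors]
        simple = train_simple(blast_col, labels, seed=ec_seed)
        ranking = rank_importance(forest)
        rf_sdrs = extract_rf_sdrs(ranking, schema, sites)
        models.predictors[ec] = EnzymePredictor(
            spec=spec, forest=forest, simple=simple, ranking=ranking, rf_sdrs=rf_sdrs
        )
        logger.info(
            "trained %s: n=%d attributes, OOB error %.3f, %d rf-SDRs",
            ec, schema.n, forest.oob_error_, len(rf_sdrs),
        )
    return models


def evaluate_superfamily(
    models: SuperfamilyModels,
    queries: Optional[Sequence[SequenceRecord]] = None,
) -> dict[str, dict[str, list[PredictionResult]]]:
    """Run every predictor over the queries (default: the held-out test split).

    Returns per enzyme the forest's and the baseline's PredictionResults,
    each carrying the query's MTTSI to that enzyme's training positives.
    """
    if queries is None:
        queries = []
        for g in models.dataset.groups:
            queries.extend(models.dataset.test_members(g.ec))
    out: dict[str, dict[str, list[PredictionResult]]] = {}
    for ec, predictor in models.predictors.items():
        positives = predictor.spec.training_positives
        forest_results, simple_results = [], []
        for query in queries:
            vec = predictor.attribute_vector(query, mode="prediction")
            mttsi = compute_mttsi(query, positives)
            true = int(query.ec == ec)
            frac = float(predictor.forest.predict_vote_fraction(vec.values[None, :])[0])
            forest_results.append(
                PredictionResult(
                    query_id=query.id, target_ec=ec, true_label=true,
                    predicted_label=int(frac > 0.5), vote_fraction=frac, mttsi=mttsi,
                )
            )
            simple_label = int(predictor.simple.predict([[vec.values[0]]])[0])
            simple_results.append(
                PredictionResult(
                    query_id=query.id, target_ec=ec, true_label=true,
                    predicted_label=simple_label, vote_fraction=float(simple_label), mttsi=mttsi,
                )
            )
        out[ec] = {"forest": forest_results, "simple": simple_results}
    return out


def macro_bin_summary(
    results: Mapping[str, Mapping[str, Sequence[PredictionResult]]],
    model: str = "forest",
    metric: str = "precision",
):
    """Macro-averaged per-bin metric over enzymes (see evaluation.macro_average)."""
    per_enzyme = [bin_results(res[model]) for res in results.values()]
    return macro_average(per_enzyme, metric=metric)
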
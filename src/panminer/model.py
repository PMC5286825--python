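"""High-level modelling interface: build a miner from data, fit, inspect.

:class:`PathwaySetMiner` bundles the whole pipeline — enrichment-based
pathway selection, CORG activity inference, discretization and 2n-bit
encoding, per-class BiMax mining, rule filtering and ranking, PAN
construction — behind a ``fit()`` call that returns a results object
carrying every intermediate product plus a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import activity as _activity
from .bimax import Bicluster, mine_class_biclusters
from . import classify_eval as _classify
from . import enrichment as _enrichment
from . import pan as _pan
from . import rulemining as _rules
from .io_formats import (CASE, CONTROL, GeneSetCollection, OmicsMatrix,
                         read_gmt, read_labels, read_matrix, preprocess)

logger = logging.getLogger(__name__)


@dataclass
class MinerConfig:
    """Tunable thresholds of the pipeline (defaults are the method's)."""

    q_threshold: float = 0.05
    n_perm: int = 1000
    weight_exponent: float = 1.0
    min_set_size: int = 5
    min_support: float = 0.25
    min_pathways: int = 2
    min_confidence: float = 0.8
    min_lift: float = 1.0
    top_n: int = 250
    variance_threshold: float = 0.0


class PathwaySetMiner:
    """Mine class-specific pathway-set markers from one omics matrix.

    Parameters
    ----------
    matrix : OmicsMatrix
        Gene-level matrix with case/control labels.  Rows are z-scored
        during ``fit`` if they are not already centered.
    gene_sets : GeneSetCollection
        Candidate pathways (e.g. a curated MSigDB-style collection).
    """

    def __init__(self, matrix: OmicsMatrix, gene_sets: GeneSetCollection,
                 config: MinerConfig | None = None, **overrides):
        cfg = config or MinerConfig()
        for key, value in overrides.items():
            if not hasattr(cfg, key):
                raise TypeError(f"unknown configuration option {key!r}")
            setattr(cfg, key, value)
        self.config = cfg
        self.gene_sets = gene_sets
        self.matrix = self._ensure_normalized(matrix)

    @classmethod
    def from_files(cls, matrix_path, labels_path, gmt_path,
                   datatype: str = "expression", **kwargs) -> "PathwaySetMiner":
        labels = read_labels(labels_path)
        matrix = read_matrix(matrix_path, labels=labels, datatype=datatype)
        return cls(matrix, read_gmt(gmt_path), **kwargs)

    def _ensure_normalized(self, matrix: OmicsMatrix) -> OmicsMatrix:
        means = matrix.values.mean(axis=1)
        sds = matrix.values.std(axis=1, ddof=1)
        if (means.abs() < 1e-9).all() and ((sds - 1).abs() < 1e-6).all():
            return matrix
        return preprocess(matrix,
                          variance_threshold=self.config.variance_threshold)

    # -- pipeline stages -------------------------------------------------

    def select_pathways(self, seed: int = 0) -> tuple[list[str], dict]:
        """Permutation GSEA under both ranking metrics; intersect."""
        cfg = self.config
        results = {}
        for metric in ("snr", "tstat"):
            results[metric] = _enrichment.permutation_enrichment(
                self.matrix, self.gene_sets, metric=metric,
                n_perm=cfg.n_perm, seed=seed,
                weight_exponent=cfg.weight_exponent,
                min_set_size=cfg.min_set_size,
            )
        significant = _enrichment.select_significant_pathways(
            results["snr"], results["tstat"], cfg.q_threshold)
        return significant, results

    def fit(self, seed: int = 0, pathways: Sequence[str] | None = None,
            ) -> "PathwaySetMiningResults":
        """Run the full pipeline.

        ``pathways`` overrides the enrichment stage with a pre-selected
        significant-pathway list (e.g. the union over expression and
        methylation runs of a paired design).
        """
        cfg = self.config
        enrichment_results: dict = {}
        if pathways is None:
            pathways, enrichment_results = self.select_pathways(seed=seed)
            if not pathways:
                raise ValueError(
                    "no significant pathway at q<%g; cannot mine" % cfg.q_threshold)
        profile = _activity.pathway_activity_profile(
            self.matrix, self.gene_sets, pathways)
        states = _activity.discretize_activity(profile)
        bits = _activity.binarize(states)
        biclusters = mine_class_biclusters(
            bits, self.matrix.labels, min_pathways=cfg.min_pathways,
            min_support=cfg.min_support)
        rules = _rules.generate_rules(biclusters, bits, self.matrix.labels,
                                      min_conf=cfg.min_confidence,
                                      min_lift=cfg.min_lift)
        rules = _rules.deduplicate_cross_class(rules)
        markers = _rules.rank_and_select(rules, top_n=cfg.top_n)
        return PathwaySetMiningResults(
            model=self, seed=seed, significant_pathways=list(pathways),
            enrichment=enrichment_results, profile=profile, states=states,
            bits=bits, biclusters=biclusters, rules=rules, markers=markers,
        )


@dataclass
class PathwaySetMiningResults:
    """Everything the miner produced, stage by stage."""

    model: PathwaySetMiner
    seed: int
    significant_pathways: list[str]
    enrichment: dict
    profile: _activity.PathwayActivityProfile
    states: _activity.DiscretizedActivity
    bits: _activity.BinaryTransactionMatrix
    biclusters: dict[str, list[Bicluster]]
    rules: list[_rules.AssociationRule]
    markers: list[_rules.PathwaySetMarker] = field(default_factory=list)

    @property
    def labels(self) -> Mapping[str, str]:
        return self.model.matrix.labels

    def class_markers(self, klass: str) -> list[_rules.PathwaySetMarker]:
        return [m for m in self.markers if m.klass == klass]

    def build_pan(self, klass: str) -> _pan.PAN:
        return _pan.build_pan(self.class_markers(klass), self.profile,
                              self.labels, klass, states=self.states)

    def pans(self) -> dict[str, _pan.PAN]:
        out = {}
        for klass in (CASE, CONTROL):
            if self.class_markers(klass):
                out[klass] = self.build_pan(klass)
        return out

    def classify(self, classifier: str = "svm", marker_type: str = "pathway_sets",
                 gene_markers: Sequence[str] | None = None,
                 n_folds: int = 4, n_reps: int = 8, seed: int = 0,
                 ) -> _classify.ClassificationReport:
        """Cross-validated evaluation of a marker type on this dataset."""
        if marker_type == "pathway_sets":
            markers = self.markers
        elif marker_type == "pathways":
            markers = self.significant_pathways
        elif marker_type == "genes":
            markers = gene_markers  # None -> fold-internal selection
        else:
            raise ValueError(f"unknown marker type {marker_type!r}")
        return _classify.evaluate_markers(
            marker_type, markers, self.profile, self.model.matrix,
            self.labels, classifier, n_folds=n_folds, n_reps=n_reps,
            seed=seed)

    def marker_table(self) -> pd.DataFrame:
        rows = [m.to_dict() for m in self.markers]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Pathway-set mining results",
            "=" * 60,
            f"samples: {len(self.model.matrix.samples)} "
            f"({len(self.model.matrix.class_samples(CASE))} case / "
            f"{len(self.model.matrix.class_samples(CONTROL))} control)",
            f"candidate pathways: {len(self.model.gene_sets)}",
            f"significant pathways: {len(self.significant_pathways)}",
            f"thresholds: support>={cfg.min_support:.2f} (class-relative), "
            f"confidence>={cfg.min_confidence:.2f}, lift>{cfg.min_lift:.2f}",
        ]
        for klass in (CASE, CONTROL):
            ms = self.class_markers(klass)
            lines.append(f"{klass} biclusters: {len(self.biclusters.get(klass, []))}; "
                         f"markers kept: {len(ms)}")
            for m in ms[:5]:
                lines.append(
                    f"  #{m.rank} {{{', '.join(m.itemset)}}} => {klass}  "
                    f"support={m.rule.support:.3f} conf={m.rule.confidence:.3f} "
                    f"lift={m.rule.lift:.3f}")
        return "\n".join(lines)
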
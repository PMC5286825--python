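"""Synthetic two-class omics data with planted pathway structure.

The generator emulates the statistical regime the mining pipeline
assumes: a case/control cohort, background genes drawn from a standard
normal, "active" pathways whose member genes are mean-shifted in one
class, and planted pathway-SETS — groups of direction-annotated pathways
that switch on together, per sample, with a given penetrance in their
class and a small leak rate in the other.  An optional methylation matrix
mirrors the expression signal with flipped sign, mimicking the inverse
expression/methylation relationship seen in paired designs.  Every run is
fully determined by the seed, and the returned ground-truth record lists
the planted pathways, sets and per-sample module states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .activity import make_item, parse_item
from .io_formats import CASE, CONTROL, GeneSetCollection, OmicsMatrix


@dataclass(frozen=True)
class PlantedSet:
    """A ground-truth pathway-set: signed items co-activated per sample."""

    items: tuple[str, ...]  # e.g. ("P1:up", "P2:up", "P3:down")
    klass: str = CASE
    penetrance: float = 0.8
    leak: float = 0.05

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("planted set needs at least one item")
        if self.klass not in (CASE, CONTROL):
            raise ValueError("class must be case or control")
        if not (0 <= self.leak < self.penetrance <= 1):
            raise ValueError("need 0 <= leak < penetrance <= 1")
        for item in self.items:
            parse_item(item)  # validates the suffix


@dataclass(frozen=True)
class PlantedPathway:
    """A class-level active pathway: all member genes shifted in one class."""

    pathway: str
    klass: str = CASE
    delta: float = 2.0
    direction: int = 1

    def __post_init__(self) -> None:
        if self.klass not in (CASE, CONTROL):
            raise ValueError("class must be case or control")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class SyntheticConfig:
    """Study-design knobs for the generator.

    Defaults follow a paired tumor/normal microarray regime: ~40 pathways
    of 25 genes each, 40 case and 40 control samples, effect sizes in
    units of the background standard deviation.
    """

    n_case: int = 40
    n_control: int = 40
    n_pathways: int = 40
    genes_per_pathway: int = 25
    n_background_genes: int = 500
    delta: float = 2.0            # mean shift (sd units) for planted signal
    noise_sd: float = 1.0
    planted_pathways: tuple[PlantedPathway, ...] = ()
    planted_sets: tuple[PlantedSet, ...] = ()
    methylation_mirror: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_case, self.n_control, self.n_pathways,
               self.genes_per_pathway) < 1:
            raise ValueError("counts must be positive")
        known = {f"P{i + 1}" for i in range(self.n_pathways)}
        for pp in self.planted_pathways:
            if pp.pathway not in known:
                raise ValueError(f"planted pathway {pp.pathway!r} does not exist")
        for ps in self.planted_sets:
            for item in ps.items:
                if parse_item(item)[0] not in known:
                    raise ValueError(f"planted set references unknown {item!r}")


@dataclass
class GroundTruth:
    """What was planted, for judging recovery."""

    planted_pathways: list[PlantedPathway]
    planted_sets: list[PlantedSet]
    module_states: dict[str, dict[str, bool]]  # set key -> sample -> on?

    def to_dict(self) -> dict:
        return {
            "planted_pathways": [asdict(p) for p in self.planted_pathways],
            "planted_sets": [asdict(s) for s in self.planted_sets],
            "module_states": self.module_states,
        }


@dataclass
class SyntheticDataset:
    expression: OmicsMatrix
    methylation: OmicsMatrix | None
    gene_sets: GeneSetCollection
    truth: GroundTruth
    labels: dict[str, str] = field(default_factory=dict)


def _set_key(ps: PlantedSet) -> str:
    return "+".join(ps.items) + "=>" + ps.klass


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset.  Identical config (incl. seed) -> identical output."""
    rng = np.random.default_rng(config.seed)
    samples = ([f"case_{i + 1}" for i in range(config.n_case)]
               + [f"ctrl_{i + 1}" for i in range(config.n_control)])
    labels = {s: (CASE if s.startswith("case_") else CONTROL) for s in samples}
    class_of = np.array([labels[s] for s in samples])

    pathways = [f"P{i + 1}" for i in range(config.n_pathways)]
    sets = {p: [f"{p}_G{j + 1}" for j in range(config.genes_per_pathway)]
            for p in pathways}
    genes = [g for p in pathways for g in sets[p]]
    genes += [f"BG_{k + 1}" for k in range(config.n_background_genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}

    shift = np.zeros((len(genes), len(samples)))
    for pp in config.planted_pathways:
        rows = [gene_pos[g] for g in sets[pp.pathway]]
        cols = class_of == pp.klass
        shift[np.ix_(rows, np.flatnonzero(cols))] += pp.direction * pp.delta

    module_states: dict[str, dict[str, bool]] = {}
    for ps in config.planted_sets:
        on_prob = np.where(class_of == ps.klass, ps.penetrance, ps.leak)
        on = rng.random(len(samples)) < on_prob
        module_states[_set_key(ps)] = {s: bool(o) for s, o in zip(samples, on)}
        for item in ps.items:
            pathway, direction = parse_item(item)
            rows = [gene_pos[g] for g in sets[pathway]]
            shift[np.ix_(rows, np.flatnonzero(on))] += direction * config.delta

    expr_vals = shift + rng.normal(0.0, config.noise_sd,
                                   size=(len(genes), len(samples)))
    expression = OmicsMatrix(
        pd.DataFrame(expr_vals, index=genes, columns=samples),
        labels, "expression",
    )

    methylation = None
    if config.methylation_mirror:
        meth_vals = -shift + rng.normal(0.0, config.noise_sd,
                                        size=(len(genes), len(samples)))
        methylation = OmicsMatrix(
            pd.DataFrame(meth_vals, index=genes, columns=samples),
            labels, "methylation",
        )

    collection = GeneSetCollection(sets, {p: f"synthetic pathway {p}"
                                          for p in pathways})
    truth = GroundTruth(list(config.planted_pathways),
                        list(config.planted_sets), module_states)
    return SyntheticDataset(expression, methylation, collection, truth, labels)


def default_recovery_config(seed: int = 0, n_case: int = 40,
                            n_control: int = 40,
                            extra_active_pathways: int = 0) -> SyntheticConfig:
    """The standard planted-set scenario: one case-specific signed
    pathway-set {P1 up, P2 up, P3 down} switching on with penetrance 0.8
    in cases and leaking into 5% of controls, among background noise
    pathways.  ``extra_active_pathways`` additionally plants that many
    class-level differentially-active pathways (a richer demo scenario
    where the module competes with ordinary markers)."""
    planted_set = PlantedSet(items=(make_item("P1", 1), make_item("P2", 1),
                                    make_item("P3", -1)),
                             klass=CASE, penetrance=0.8, leak=0.05)
    extra = tuple(
        PlantedPathway(pathway=f"P{i}", klass=CASE, delta=1.5,
                       direction=1 if i % 2 else -1)
        for i in range(4, 4 + extra_active_pathways)
    )
    return SyntheticConfig(
        n_case=n_case, n_control=n_control, n_pathways=20,
        genes_per_pathway=15, n_background_genes=200, delta=2.0,
        planted_sets=(planted_set,), planted_pathways=extra, seed=seed,
    )
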
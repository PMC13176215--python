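"""Synthetic multi-cohort expression data with known ground truth.

Generates log2-scale gene-by-sample matrices that emulate the structure of a
multi-dataset cartilage transcriptomics study: several batches with
additive + multiplicative per-gene batch effects, a graded degradation
spectrum (healthy -> early -> advanced), a planted set of differentially
expressed genes, a strain-vs-control mini-cohort in which a subset of those
genes responds to mechanical stress, and gene-set collections overlapping the
planted signal. Every downstream stage of the pipeline is testable against
the returned ground truth without any external download.

The generative model for gene g, sample s in batch b is

    y[g, s] = mu_g
              + grade(s) * sign(g) * deg_effect * 1[g in DEG]
              + strain(s) * strain_effect * 1[g in mechano]
              + gamma[b, g] + delta[b, g] * eps,    eps ~ N(0, noise_sd)

which is exactly the additive + multiplicative location/scale form assumed by
the empirical-Bayes batch corrector, so correction can be tested as a
parameter-recovery problem.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "PathwayCollection",
    "generate_multibatch_expression",
    "generate_null_cohort",
    "generate_pathway_collection",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_metadata_tsv",
    "read_metadata_tsv",
]

#: degradation grade attached to each condition label (0 = healthy,
#: mid-range for early/meniscectomy-like damage, 1 = advanced disease)
DEFAULT_GRADES = {"healthy": 0.0, "early": 0.4, "advanced": 1.0}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic multi-batch cohort.

    Defaults mirror the shape of the study the pipeline targets at desk
    scale: six tissue datasets (first three in the training role) plus one
    strain mini-cohort, 93 planted DEGs split 74 up / 19 down, 16 of them
    strain-responsive, |log2FC| of 1.0 at full grade.
    """

    n_genes: int = 2000
    n_datasets: int = 6
    n_train_datasets: int = 3
    samples_per_condition: dict = field(
        default_factory=lambda: {"healthy": 10, "early": 4, "advanced": 10}
    )
    baseline_mean_range: tuple = (4.0, 12.0)
    #: relative per-gene dispersion multipliers applied to ``noise_sd``
    baseline_sd_range: tuple = (1.0, 1.0)
    batch_shift_sd: float = 2.0
    batch_scale_sd: float = 0.3
    n_deg_up: int = 74
    n_deg_down: int = 19
    deg_effect: float = 1.0
    n_mechano: int = 16
    #: disease-effect multiplier for strain-responsive genes: mechanosensitive
    #: genes are the strongest degradation drivers, so they rank at the top of
    #: model attention as well as of the strain response
    mechano_deg_boost: float = 2.0
    strain_effect: float = 1.0
    strain_samples_per_group: int = 9
    noise_sd: float = 0.5
    grades: dict = field(default_factory=lambda: dict(DEFAULT_GRADES))
    class_grade_threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_datasets": self.n_datasets,
            "n_deg_up": self.n_deg_up,
            "n_deg_down": self.n_deg_down,
            "n_mechano": self.n_mechano,
            "strain_samples_per_group": self.strain_samples_per_group,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"invariant violated: {name} >= 0 (got {value})")
        if self.n_deg_up + self.n_deg_down > self.n_genes:
            raise ValueError(
                "invariant violated: n_deg_up + n_deg_down <= n_genes "
                f"({self.n_deg_up} + {self.n_deg_down} > {self.n_genes})"
            )
        if self.n_mechano > self.n_deg_up + self.n_deg_down:
            raise ValueError(
                "invariant violated: n_mechano <= n_deg_up + n_deg_down "
                f"({self.n_mechano} > {self.n_deg_up + self.n_deg_down})"
            )
        if self.n_train_datasets > self.n_datasets:
            raise ValueError(
                "invariant violated: n_train_datasets <= n_datasets"
            )
        for cond in self.samples_per_condition:
            if cond not in self.grades:
                raise ValueError(f"condition {cond!r} has no grade assigned")
        for g in self.grades.values():
            if not 0.0 <= g <= 1.0:
                raise ValueError("invariant violated: grades lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth of a synthetic cohort.

    ``deg_genes`` lists ``(gene, direction)`` with direction in {+1, -1};
    every mechano gene is a DEG gene; grades lie in [0, 1].
    ``batch_params[(batch, gene)] = (additive shift, scale factor)``.
    """

    deg_genes: list
    mechano_genes: list
    grade_per_sample: dict
    batch_params: dict

    @property
    def deg_symbols(self) -> list:
        return [g for g, _ in self.deg_genes]

    def to_json(self, path) -> None:
        payload = {
            "deg_genes": [[g, int(d)] for g, d in self.deg_genes],
            "mechano_genes": list(self.mechano_genes),
            "grade_per_sample": {s: float(g) for s, g in self.grade_per_sample.items()},
            "batch_params": {
                f"{b}\t{g}": [float(a), float(m)]
                for (b, g), (a, m) in self.batch_params.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            deg_genes=[(g, int(d)) for g, d in payload["deg_genes"]],
            mechano_genes=payload["mechano_genes"],
            grade_per_sample=payload["grade_per_sample"],
            batch_params={
                tuple(k.split("\t")): tuple(v)
                for k, v in payload["batch_params"].items()
            },
        )


@dataclass
class PathwayCollection:
    """Named gene sets (term -> member symbols) with a collection label."""

    label: str
    sets: dict

    def __post_init__(self):
        for term, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"empty gene set: {term!r}")


def _gene_names(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_multibatch_expression(spec: CohortSpec):
    """Generate a multi-batch cohort; returns (expression, metadata, truth).

    Expression is a genes x samples DataFrame (log2 scale); metadata is a
    per-sample DataFrame with columns batch, condition, class, role.  The
    strain mini-cohort (control vs strain at fixed mid-range grade) is
    appended as its own batch with role ``strain``.  Deterministic given
    ``spec`` (including its seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)

    # planted gene sets
    n_deg = spec.n_deg_up + spec.n_deg_down
    deg_idx = rng.choice(spec.n_genes, size=n_deg, replace=False)
    directions = np.concatenate(
        [np.ones(spec.n_deg_up, dtype=int), -np.ones(spec.n_deg_down, dtype=int)]
    )
    deg_genes = [(genes[i], int(d)) for i, d in zip(deg_idx, directions)]
    mech_pick = rng.choice(n_deg, size=spec.n_mechano, replace=False)
    mechano_genes = [genes[deg_idx[i]] for i in mech_pick]

    mu = rng.uniform(*spec.baseline_mean_range, size=spec.n_genes)
    sd_scale = rng.uniform(*spec.baseline_sd_range, size=spec.n_genes)

    effect = np.zeros(spec.n_genes)
    effect[deg_idx] = directions * spec.deg_effect
    mech_idx = [deg_idx[i] for i in mech_pick]
    effect[mech_idx] *= spec.mechano_deg_boost
    strain_mask_genes = np.zeros(spec.n_genes)
    strain_mask_genes[mech_idx] = spec.strain_effect

    # sample layout
    batches, conditions, grades_vec, strain_vec, roles, sample_ids = [], [], [], [], [], []
    for d in range(spec.n_datasets):
        batch = f"d{d + 1}"
        role = "train" if d < spec.n_train_datasets else "validation"
        for cond in sorted(spec.samples_per_condition):
            for i in range(spec.samples_per_condition[cond]):
                sample_ids.append(f"{batch}_{cond}_{i + 1}")
                batches.append(batch)
                conditions.append(cond)
                grades_vec.append(spec.grades[cond])
                strain_vec.append(0.0)
                roles.append(role)
    mid_grade = spec.grades.get("early", 0.4)
    for cond, strained in (("control", 0.0), ("strain", 1.0)):
        for i in range(spec.strain_samples_per_group):
            sample_ids.append(f"strain_{cond}_{i + 1}")
            batches.append("strain")
            conditions.append(cond)
            grades_vec.append(mid_grade)
            strain_vec.append(strained)
            roles.append("strain")

    grades_vec = np.asarray(grades_vec)
    strain_vec = np.asarray(strain_vec)
    n_samples = len(sample_ids)

    # per-batch location/scale effects
    batch_names = [f"d{d + 1}" for d in range(spec.n_datasets)] + (
        ["strain"] if spec.strain_samples_per_group > 0 else []
    )
    gamma = {
        b: rng.normal(0.0, spec.batch_shift_sd, size=spec.n_genes)
        for b in batch_names
    }
    delta = {
        b: np.exp(rng.normal(0.0, spec.batch_scale_sd, size=spec.n_genes))
        for b in batch_names
    }

    values = np.empty((spec.n_genes, n_samples))
    eps = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))
    for j, (b, g, st) in enumerate(zip(batches, grades_vec, strain_vec)):
        values[:, j] = (
            mu
            + g * effect
            + st * strain_mask_genes
            + gamma[b]
            + delta[b] * sd_scale * eps[:, j]
        )

    expression = pd.DataFrame(
        values, index=pd.Index(genes, name="gene"), columns=sample_ids
    )
    metadata = pd.DataFrame(
        {
            "batch": batches,
            "condition": conditions,
            "class": (grades_vec >= spec.class_grade_threshold).astype(int),
            "role": roles,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    batch_params = {
        (b, genes[i]): (float(gamma[b][i]), float(delta[b][i]))
        for b in batch_names
        for i in range(spec.n_genes)
    }
    truth = GroundTruth(
        deg_genes=deg_genes,
        mechano_genes=mechano_genes,
        grade_per_sample=dict(zip(sample_ids, grades_vec.tolist())),
        batch_params=batch_params,
    )
    return expression, metadata, truth


def generate_null_cohort(spec: CohortSpec):
    """Cohort with no planted class or strain signal (labels independent of
    expression); ``GroundTruth.deg_genes`` and ``mechano_genes`` are empty."""
    null_spec = dataclasses.replace(spec, deg_effect=0.0, strain_effect=0.0)
    expression, metadata, truth = generate_multibatch_expression(null_spec)
    truth.deg_genes = []
    truth.mechano_genes = []
    return expression, metadata, truth


def generate_pathway_collection(
    genes,
    truth: GroundTruth,
    n_sets: int,
    enriched_fraction: float,
    seed: int,
    set_size_range=(10, 40),
    label: str = "synthetic",
) -> PathwayCollection:
    """Gene-set collection with a planted fraction of DEG-enriched terms.

    Enriched terms draw their members from ``truth.deg_genes`` first (falling
    back to the remaining universe once the DEG pool is exhausted), so their
    overlap with the planted signal exceeds the hypergeometric expectation;
    the remaining terms are uniform draws from the universe.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if not 0.0 <= enriched_fraction <= 1.0:
        raise ValueError("enriched_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = list(genes)
    deg = [g for g in truth.deg_symbols if g in set(universe)]
    non_deg = [g for g in universe if g not in set(deg)]
    n_enriched = int(round(enriched_fraction * n_sets))
    sets = {}
    for k in range(n_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        size = min(size, len(universe))
        if k < n_enriched and deg:
            n_from_deg = min(size, len(deg))
            members = list(rng.choice(deg, size=n_from_deg, replace=False))
            if size > n_from_deg:
                members += list(
                    rng.choice(non_deg, size=size - n_from_deg, replace=False)
                )
            term = f"{label}_enriched_{k + 1}"
        else:
            members = list(rng.choice(universe, size=size, replace=False))
            term = f"{label}_set_{k + 1}"
        sets[term] = sorted(members)
    return PathwayCollection(label=label, sets=sets)


# ---------------------------------------------------------------------------
# plain-text I/O


def write_expression_tsv(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
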
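"""Synthetic two-condition bulk RNA-seq experiments with known ground truth.

The generator emulates the design of a FACS-enriched sensory-neuron study:
condition A (dorsal root ganglion neurons, 6 replicates by default) versus
condition B (trigeminal ganglion neurons, 4 replicates), negative-binomial
counts, a mixture of shared, fold-changed, condition-exclusive, silent and
glial-contaminant genes, an optional per-sample contamination admixture, a
matched pure-neuron reference presence set, and an ortholog comparison table
with configurable trend concordance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Ground-truth gene classes, in the fixed order used for largest-remainder
#: rounding and tie-breaking.
CLASSES = (
    "common",
    "de_up_a",
    "de_up_b",
    "exclusive_a",
    "exclusive_b",
    "glial_contaminant",
    "silent",
)

#: Classes whose genes carry a true between-condition difference.
DE_CLASSES = ("de_up_a", "de_up_b", "exclusive_a", "exclusive_b")

DEFAULT_PROPORTIONS: dict[str, float] = {
    "common": 0.70,
    "de_up_a": 0.05,
    "de_up_b": 0.05,
    "exclusive_a": 0.025,
    "exclusive_b": 0.025,
    "glial_contaminant": 0.05,
    "silent": 0.10,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated two-condition experiment.

    Parameters
    ----------
    n_genes
        Number of genes in the simulated annotation.
    n_reps_a, n_reps_b
        Replicates per condition (defaults 6 and 4, the study design this
        generator emulates). Both must be at least 2, because the
        presence-call rule requires two replicates per condition.
    class_proportions
        Mapping over the ground-truth classes in :data:`CLASSES`; must be
        non-negative and sum to 1 (within 1e-9). Counts per class are made
        exact by largest-remainder rounding.
    baseline_mean_log_range
        Natural-log range from which per-gene baseline expression means are
        drawn log-uniformly (expressed counts at the reference depth).
    de_log2fc_magnitude
        True \\|log2 fold change\\| for the ``de_up_a``/``de_up_b`` classes,
        split symmetrically around the baseline mean.
    dispersion
        Negative-binomial dispersion alpha shared across genes
        (variance = mu + alpha * mu**2); 0 gives Poisson counts.
    library_size_range
        Range from which per-sample library sizes are drawn log-uniformly.
        Only their ratios matter: each sample's expected counts are the gene
        means scaled by its library size relative to the geometric mean.
    gene_length_range
        Uniform range (bp) for annotated union-exon gene lengths.
    contamination_fraction
        Fraction of each sample's expected counts drawn from a glial
        expression profile (glial-contaminant genes receive counts only
        through this admixture).
    contamination_bias
        Multiplier on the contamination fraction in condition B (capped at a
        total fraction of 1). Values other than 1 emulate a between-ganglion
        difference in tissue composition — the mechanism that makes
        glial-driven genes appear differentially expressed in whole-tissue
        comparisons.
    seed
        Seed for the generator; identical configs give bit-identical output.
    """

    n_genes: int = 2000
    n_reps_a: int = 6
    n_reps_b: int = 4
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    baseline_mean_log_range: tuple[float, float] = (math.log(5.0), math.log(2000.0))
    de_log2fc_magnitude: float = 1.0
    dispersion: float = 0.2
    library_size_range: tuple[int, int] = (5_000_000, 20_000_000)
    gene_length_range: tuple[int, int] = (500, 5000)
    contamination_fraction: float = 0.0
    contamination_bias: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if self.n_reps_a < 2 or self.n_reps_b < 2:
            raise ConfigurationError(
                "each condition needs at least 2 replicates for the presence-call rule"
            )
        props = dict(self.class_proportions)
        unknown = set(props) - set(CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown gene classes: {sorted(unknown)}")
        values = [float(props.get(c, 0.0)) for c in CLASSES]
        if any(v < 0 for v in values):
            raise ConfigurationError("class proportions must be non-negative")
        if abs(sum(values) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class proportions must sum to 1, got {sum(values)!r}"
            )
        if self.de_log2fc_magnitude <= 0:
            raise ConfigurationError("de_log2fc_magnitude must be positive")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be non-negative")
        if not (0.0 <= self.contamination_fraction <= 1.0):
            raise ConfigurationError("contamination_fraction must lie in [0, 1]")
        if self.contamination_bias <= 0:
            raise ConfigurationError("contamination_bias must be positive")
        lo, hi = self.baseline_mean_log_range
        if not lo <= hi:
            raise ConfigurationError("baseline_mean_log_range must be ordered")
        for name in ("library_size_range", "gene_length_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"{name} must be positive and ordered")


@dataclass
class SimulatedExperiment:
    """A simulated experiment together with its ground truth.

    Attributes
    ----------
    counts
        genes x samples integer count matrix (DataFrame).
    conditions
        Per-sample condition label, 'A' or 'B', indexed like the columns.
    annotation
        gene_id-indexed table with ``symbol``, ``length_bp``, ``family``.
    truth
        gene_id-indexed table with ``symbol``, ``true_class``,
        ``true_log2fc`` (B vs A; NaN for exclusives, whose effect is
        conveyed by the class label) and ``neuronal``.
    reference_presence
        Gene ids expressed in the emulated pure-neuron reference dataset.
    comparison
        Ortholog comparison table indexed by upper-cased symbol with mean
        FPKM per condition (``fpkm_a``, ``fpkm_b``).
    config
        The :class:`SimConfig` that produced the experiment.
    """

    counts: pd.DataFrame
    conditions: pd.Series
    annotation: pd.DataFrame
    truth: pd.DataFrame
    reference_presence: frozenset[str]
    comparison: pd.DataFrame
    config: SimConfig


def largest_remainder_counts(proportions: Mapping[str, float], total: int) -> dict[str, int]:
    """Apportion ``total`` items over classes so counts are exact integers.

    Largest-remainder (Hamilton) rounding: floor each quota, then hand the
    leftover units to the classes with the largest fractional remainders,
    ties broken by the fixed :data:`CLASSES` order.
    """
    quotas = {c: float(proportions.get(c, 0.0)) * total for c in CLASSES}
    counts = {c: int(math.floor(q)) for c, q in quotas.items()}
    leftover = total - sum(counts.values())
    remainders = sorted(
        CLASSES, key=lambda c: (-(quotas[c] - counts[c]), CLASSES.index(c))
    )
    for c in remainders[:leftover]:
        counts[c] += 1
    return counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial counts with variance mu + alpha*mu^2 (Poisson if 0)."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if alpha == 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    r = 1.0 / alpha
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def generate_counts(config: SimConfig) -> SimulatedExperiment:
    """Generate a full simulated experiment from a :class:`SimConfig`.

    Expected counts for a neuronal gene with baseline mean ``mu`` in a sample
    of relative library size ``s`` are ``s * mu * (1 - contamination_fraction)``
    (scaled by the configured fold change in its favored condition);
    glial-contaminant genes receive counts only through the contamination
    admixture, which redirects ``contamination_fraction`` of each sample's
    expected total into a fixed glial profile.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    class_counts = largest_remainder_counts(config.class_proportions, n)
    labels = np.concatenate(
        [np.repeat(c, class_counts[c]) for c in CLASSES]
    )
    labels = labels[rng.permutation(n)]

    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    symbols = np.array([f"Gene{i}" for i in range(n)])
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n
    )

    lo, hi = config.baseline_mean_log_range
    base_mu = np.exp(rng.uniform(lo, hi, size=n))
    fc = config.de_log2fc_magnitude
    half = 2.0 ** (fc / 2.0)

    mean_a = np.zeros(n)
    mean_b = np.zeros(n)
    for cls, ma, mb in (
        ("common", 1.0, 1.0),
        ("de_up_a", half, 1.0 / half),
        ("de_up_b", 1.0 / half, half),
        ("exclusive_a", 1.0, 0.0),
        ("exclusive_b", 0.0, 1.0),
    ):
        mask = labels == cls
        mean_a[mask] = base_mu[mask] * ma
        mean_b[mask] = base_mu[mask] * mb

    # Glial profile: contaminant genes drawn from the upper half of the
    # baseline range (glia-enriched transcripts tend to be abundant).
    glial_mask = labels == "glial_contaminant"
    glial_profile = np.zeros(n)
    if glial_mask.any():
        mid = (lo + hi) / 2.0
        glial_profile[glial_mask] = np.exp(
            rng.uniform(mid, hi, size=int(glial_mask.sum()))
        )

    lib_lo, lib_hi = config.library_size_range
    libs = np.exp(
        rng.uniform(math.log(lib_lo), math.log(lib_hi), size=config.n_reps_a + config.n_reps_b)
    )
    rel_size = libs / np.exp(np.mean(np.log(libs)))

    sample_names = [f"A{i + 1}" for i in range(config.n_reps_a)] + [
        f"B{i + 1}" for i in range(config.n_reps_b)
    ]
    conditions = pd.Series(
        ["A"] * config.n_reps_a + ["B"] * config.n_reps_b,
        index=sample_names,
        name="condition",
    )

    c_by_cond = {
        "A": config.contamination_fraction,
        "B": min(1.0, config.contamination_fraction * config.contamination_bias),
    }
    counts = np.zeros((n, len(sample_names)), dtype=np.int64)
    glial_total = glial_profile.sum()
    for j, cond in enumerate(conditions):
        neu = mean_a if cond == "A" else mean_b
        c = c_by_cond[cond]
        mu = (1.0 - c) * neu
        if c > 0 and glial_total > 0:
            mu = mu + c * neu.sum() * glial_profile / glial_total
        counts[:, j] = _nb_draw(rng, rel_size[j] * mu, config.dispersion)

    true_log2fc = np.zeros(n)
    true_log2fc[labels == "de_up_a"] = -fc
    true_log2fc[labels == "de_up_b"] = fc
    true_log2fc[np.isin(labels, ["exclusive_a", "exclusive_b"])] = np.nan

    truth = pd.DataFrame(
        {
            "symbol": symbols,
            "true_class": labels,
            "true_log2fc": true_log2fc,
            "neuronal": labels != "glial_contaminant",
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    annotation = pd.DataFrame(
        {
            "symbol": symbols,
            "length_bp": lengths,
            "family": np.where(glial_mask, "glial", ""),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    counts_df = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_names
    )

    reference = generate_reference_presence(truth)
    comparison = generate_comparison(truth, concordant_fraction=0.8, seed=config.seed + 1)

    return SimulatedExperiment(
        counts=counts_df,
        conditions=conditions,
        annotation=annotation,
        truth=truth,
        reference_presence=reference,
        comparison=comparison,
        config=config,
    )


def generate_reference_presence(truth: pd.DataFrame) -> frozenset[str]:
    """Gene ids called expressed in the emulated pure-neuron reference.

    The reference mimics a magnetically-sorted neuron dataset free of glial
    contamination: it contains exactly the neuronal, non-silent genes.
    """
    keep = truth["neuronal"] & (truth["true_class"] != "silent")
    return frozenset(truth.index[keep])


def generate_comparison(
    truth: pd.DataFrame, concordant_fraction: float, seed: int
) -> pd.DataFrame:
    """Build an ortholog comparison table with controlled trend concordance.

    For each true differential gene the comparison dataset's FPKM ratio has,
    with probability ``concordant_fraction``, the same direction as the true
    fold change (and the opposite direction otherwise). Common genes get
    equal FPKM in both conditions; silent and glial genes get zero. Keys are
    upper-cased symbols, emulating symbol-based ortholog matching.
    """
    if not (0.0 <= concordant_fraction <= 1.0):
        raise ConfigurationError("concordant_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(truth)
    base = np.exp(rng.uniform(math.log(2.0), math.log(1000.0), size=n))
    ratio = 2.0 ** rng.uniform(0.5, 3.0, size=n)
    concordant = rng.random(n) < concordant_fraction

    cls = truth["true_class"].to_numpy()
    favors_a = np.isin(cls, ["de_up_a", "exclusive_a"])
    favors_b = np.isin(cls, ["de_up_b", "exclusive_b"])
    is_de = favors_a | favors_b
    # Effective direction after the concordance coin flip.
    high_in_a = np.where(concordant, favors_a, favors_b)

    fpkm_a = np.zeros(n)
    fpkm_b = np.zeros(n)
    common = cls == "common"
    fpkm_a[common] = base[common]
    fpkm_b[common] = base[common]
    de_hi_a = is_de & high_in_a
    de_hi_b = is_de & ~high_in_a
    fpkm_a[de_hi_a] = base[de_hi_a] * ratio[de_hi_a]
    fpkm_b[de_hi_a] = base[de_hi_a]
    fpkm_a[de_hi_b] = base[de_hi_b]
    fpkm_b[de_hi_b] = base[de_hi_b] * ratio[de_hi_b]

    comparison = pd.DataFrame(
        {"fpkm_a": fpkm_a, "fpkm_b": fpkm_b},
        index=pd.Index(truth["symbol"].str.upper(), name="ortholog_key"),
    )
    return comparison


def write_experiment(exp: SimulatedExperiment, outdir) -> None:
    """Write all components of a simulated experiment as plain-text files."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp.counts.to_csv(outdir / "counts.tsv", sep="\t")
    exp.conditions.to_frame().to_csv(outdir / "conditions.tsv", sep="\t")
    exp.annotation.to_csv(outdir / "annotation.tsv", sep="\t")
    exp.truth.to_csv(outdir / "truth.tsv", sep="\t")
    (outdir / "reference_presence.txt").write_text(
        "\n".join(sorted(exp.reference_presence)) + "\n"
    )
    exp.comparison.to_csv(outdir / "comparison.tsv", sep="\t")
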
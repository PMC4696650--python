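"""Synthetic multi-study expression data with a planted consensus signature.

The generator emulates the structure of a five-study microarray
meta-analysis: two platform types with unequal gene panels (three studies
measure the full panel, two measure roughly 45% of it), one to three probes
per gene, unbalanced per-study sample sizes of order 6-21 per arm, additive
log2-scale disease effects planted in a direction-consistent subset of
genes, Gaussian residual noise, and per-study batch location/scale shifts.

Each planted gene is active (carries its effect in cases) in a random set
of at least three studies among those that measure it, so the Common
Dataset Ratio filter at 0.6 can recover it.  Batch scale multiplies the
baseline-plus-noise component only; the class effect is added afterwards,
so the true per-study log2 fold change of an active gene equals its
configured effect.  A truth table records direction, per-study activity and
per-study log2FC for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import SignatureTable
from .errors import ConfigError
from .io import ExpressionDataset, ProbeAnnotation

DEFAULT_SIZES = ((21, 18), (20, 13), (12, 6), (10, 7), (10, 10))
DEFAULT_PANELS = (1.0, 1.0, 1.0, 0.45, 0.45)


@dataclass
class SimulationConfig:
    """Study-design parameters for the multi-study generator.

    Defaults echo the five-study design the pipeline targets: K = 5
    studies, sample sizes (case, control) of (21,18), (20,13), (12,6),
    (10,7), (10,10), three full-panel and two partial-panel platforms,
    2000 genes of which 200 carry a planted effect with |log2FC| uniform
    on [0.8, 2.5].
    """

    n_datasets: int = 5
    sizes: tuple[tuple[int, int], ...] = DEFAULT_SIZES
    n_genes: int = 2000
    panel_fractions: tuple[float, ...] = DEFAULT_PANELS
    n_planted: int = 200
    effect_low: float = 0.8
    effect_high: float = 2.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd_low: float = 0.3
    noise_sd_high: float = 0.8
    batch_loc_sd: float = 0.5
    batch_scale_low: float = 0.8
    batch_scale_high: float = 1.25
    min_active: int = 3
    max_probes_per_gene: int = 3
    probe_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_datasets < 2:
            raise ConfigError("need >= 2 datasets")
        if len(self.sizes) != self.n_datasets:
            raise ConfigError("sizes must list (n_case, n_control) per dataset")
        if len(self.panel_fractions) != self.n_datasets:
            raise ConfigError("panel_fractions must have one entry per dataset")
        if any(nc < 2 or nn < 2 for nc, nn in self.sizes):
            raise ConfigError("every dataset needs >= 2 samples per class")
        if not 0 <= self.n_planted <= self.n_genes:
            raise ConfigError("n_planted must be in [0, n_genes]")
        if any(not 0 < f <= 1 for f in self.panel_fractions):
            raise ConfigError("panel fractions must be in (0, 1]")
        n_full = sum(1 for f in self.panel_fractions if f == 1.0)
        if n_full < self.min_active:
            raise ConfigError(
                f"need >= {self.min_active} full panels to guarantee planted "
                "genes are measurable in enough datasets"
            )
        if self.effect_low <= 0 or self.effect_high < self.effect_low:
            raise ConfigError("effect range must satisfy 0 < low <= high")


@dataclass
class SimulationTruth:
    """Planted-gene ground truth for recovery scoring.

    ``table`` is indexed by gene with columns ``direction``, ``effect``
    (absolute log2FC), and per-study ``active_<id>`` / ``log2fc_<id>``.
    """

    table: pd.DataFrame
    dataset_ids: list[str] = field(default_factory=list)

    @property
    def planted_genes(self) -> set[str]:
        return set(self.table.index)

    def direction_of(self, gene: str) -> str:
        return str(self.table.loc[gene, "direction"])


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def simulate_multistudy(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[list[ExpressionDataset], SimulationTruth, ProbeAnnotation]:
    """Generate K studies, the planted-gene truth table and the probe map.

    Deterministic given the seed (``seed`` overrides ``config.seed``).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    G, K = config.n_genes, config.n_datasets
    genes = _gene_names(G)
    dataset_ids = [f"DS{i + 1}" for i in range(K)]

    # Gene-level parameters.
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=G)
    noise_sd = rng.uniform(config.noise_sd_low, config.noise_sd_high, size=G)
    planted_idx = rng.choice(G, size=config.n_planted, replace=False)
    planted_mask = np.zeros(G, dtype=bool)
    planted_mask[planted_idx] = True
    effect = np.zeros(G)
    effect[planted_idx] = rng.uniform(
        config.effect_low, config.effect_high, size=config.n_planted
    )
    sign = np.zeros(G)
    sign[planted_idx] = rng.choice([-1.0, 1.0], size=config.n_planted)

    # Platform panels: full panels measure everything; partial panels a
    # random gene subset.
    panels = []
    for frac in config.panel_fractions:
        if frac == 1.0:
            panels.append(np.ones(G, dtype=bool))
        else:
            panel = np.zeros(G, dtype=bool)
            chosen = rng.choice(G, size=int(round(frac * G)), replace=False)
            panel[chosen] = True
            panels.append(panel)

    # Planted activity: each planted gene is active in a random subset
    # (size >= min_active) of the studies that measure it.
    active = np.zeros((G, K), dtype=bool)
    for g in planted_idx:
        measuring = [d for d in range(K) if panels[d][g]]
        n_active = int(rng.integers(config.min_active, len(measuring) + 1))
        chosen = rng.choice(measuring, size=n_active, replace=False)
        active[g, chosen] = True

    # Probe layout: 1..max_probes per gene, jittered per-probe effects.
    probes_per_gene = rng.integers(1, config.max_probes_per_gene + 1, size=G)
    probe_gene = np.repeat(np.arange(G), probes_per_gene)
    probe_ids = [
        f"{genes[g]}_p{j + 1}"
        for g in range(G)
        for j in range(probes_per_gene[g])
    ]
    probe_offset = rng.normal(0.0, 0.25, size=len(probe_ids))
    probe_effect = effect[probe_gene] * sign[probe_gene] + np.where(
        effect[probe_gene] > 0,
        rng.normal(0.0, config.probe_jitter_sd, size=len(probe_ids)),
        0.0,
    )
    annotation = ProbeAnnotation(dict(zip(probe_ids, (genes[g] for g in probe_gene))))

    datasets = []
    for d in range(K):
        n_case, n_control = config.sizes[d]
        n = n_case + n_control
        loc = rng.normal(0.0, config.batch_loc_sd)
        scale = rng.uniform(config.batch_scale_low, config.batch_scale_high)
        keep = panels[d][probe_gene]
        pg = probe_gene[keep]
        base = baseline[pg] + probe_offset[keep]
        eps = rng.normal(0.0, 1.0, size=(keep.sum(), n)) * noise_sd[pg][:, None]
        values = loc + scale * (base[:, None] + eps)
        case_cols = np.arange(n) < n_case
        eff_col = probe_effect[keep] * active[pg, d]
        values[:, case_cols] += eff_col[:, None]
        sample_ids = [f"{dataset_ids[d]}_S{i + 1:02d}" for i in range(n)]
        frame = pd.DataFrame(
            values, index=np.array(probe_ids)[keep], columns=sample_ids
        )
        classes = pd.Series(
            np.where(case_cols, "case", "control"), index=sample_ids
        )
        datasets.append(
            ExpressionDataset(
                dataset_id=dataset_ids[d],
                platform_id="PLAT-A" if config.panel_fractions[d] == 1.0 else "PLAT-B",
                values=frame,
                sample_class=classes,
            )
        )

    truth_rows = {}
    for g in sorted(planted_idx):
        row = {
            "direction": "up" if sign[g] > 0 else "down",
            "effect": effect[g],
        }
        for d, ds_id in enumerate(dataset_ids):
            row[f"active_{ds_id}"] = bool(active[g, d])
            row[f"log2fc_{ds_id}"] = float(sign[g] * effect[g] * active[g, d])
        truth_rows[genes[g]] = row
    truth = SimulationTruth(
        table=pd.DataFrame.from_dict(truth_rows, orient="index"),
        dataset_ids=dataset_ids,
    )
    return datasets, truth, annotation


def score_recovery(
    sig: SignatureTable, truth: SimulationTruth
) -> tuple[float, float, float | None]:
    """(sensitivity, false-discovery fraction, direction accuracy).

    Sensitivity = recovered planted / planted; false-discovery fraction =
    non-planted signature members / signature size; direction accuracy is
    computed among recovered planted genes and is None when nothing was
    recovered (or the signature is empty).
    """
    planted = truth.planted_genes
    if len(sig) == 0:
        return 0.0, 0.0, None
    members = sig.directions()
    recovered = {g for g in members if g in planted}
    sensitivity = len(recovered) / len(planted) if planted else 0.0
    fdf = (len(members) - len(recovered)) / len(members)
    if not recovered:
        return sensitivity, fdf, None
    correct = sum(
        1 for g in recovered if members[g] == truth.direction_of(g)
    )
    return sensitivity, fdf, correct / len(recovered)
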
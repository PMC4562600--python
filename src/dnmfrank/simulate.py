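"""Two-condition RNA-seq count simulation with known truth.

Emulates the structure of a spike-in calibrated benchmark experiment:
negative-binomial counts for two sample groups, a configurable fraction of
genes carrying a planted log2 fold change (random sign), per-sample
sequencing-depth factors, and an appended panel of 93 spike-in transcripts
split into four subgroups of fixed, known fold change — mirroring the
two-mix external RNA control design whose subgroup ratios 4:1, 1:1, 2:3
and 1:2 correspond to log2 fold changes 2, 0, -0.58 and -1.

Counts for gene ``i`` in sample ``j`` are drawn NB with mean
``sf_j * q_i * 2^lfc_i`` (the fold-change term applying to the treatment
class only) and a common dispersion ``alpha`` (variance ``m + alpha m^2``);
``alpha = 0`` recovers Poisson noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClassLabels, CountMatrix

__all__ = ["SimulationParams", "spikein_panel", "simulate_counts"]

DEFAULT_SPIKEIN_LOGFC = (2.0, 0.0, -0.58, -1.0)


@dataclass
class SimulationParams:
    """Knobs of the two-class count simulator.

    Defaults describe a small but realistic bulk comparison: 1000 genes,
    five replicates per condition, 10% of genes differentially expressed
    at |log2 fold change| = 2, moderate overdispersion (0.1), modest
    library-size variation, plus the 93-transcript spike-in panel.
    """

    n_genes: int = 1000
    n_per_class: int = 5
    de_fraction: float = 0.1
    logfc_values: tuple[float, ...] = (2.0,)
    base_mean_range: tuple[float, float] = (10.0, 10_000.0)
    dispersion: float = 0.1
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    spikein_count: int = 93
    spikein_subgroup_logfc: tuple[float, float, float, float] = DEFAULT_SPIKEIN_LOGFC
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_per_class < 2:
            raise ValueError("need n_genes >= 1 and n_per_class >= 2")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        lo, hi = self.base_mean_range
        if not (0 < lo <= hi):
            raise ValueError("base_mean_range must be positive and ordered")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValueError("size_factor_range must be positive and ordered")
        if self.spikein_count < 0:
            raise ValueError("spikein_count must be nonnegative")
        if len(self.spikein_subgroup_logfc) != 4:
            raise ValueError("exactly four spike-in subgroups are modelled")


def spikein_panel(params: SimulationParams) -> pd.DataFrame:
    """Truth fragment for the spike-in transcripts.

    ``spikein_count`` transcripts are split as evenly as possible over the
    four subgroups (any remainder goes to the leading subgroups), each
    subgroup carrying its fixed log2 fold change.
    """
    m = params.spikein_count
    if m < 4:
        raise ValueError("a spike-in panel needs at least one member per subgroup")
    base, extra = divmod(m, 4)
    sizes = [base + (1 if g < extra else 0) for g in range(4)]
    rows = []
    i = 0
    for g, (size, lfc) in enumerate(zip(sizes, params.spikein_subgroup_logfc), start=1):
        for _ in range(size):
            rows.append(
                {
                    "gene_id": f"spikein_{i:03d}",
                    "true_logfc": lfc,
                    "is_de": lfc != 0.0,
                    "is_spikein": True,
                    "subgroup": f"mix{g}",
                }
            )
            i += 1
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0.0:
        return rng.poisson(mean)
    size = 1.0 / dispersion  # NB shape: var = m + m^2/size
    return rng.negative_binomial(size, size / (size + mean))


def simulate_counts(
    params: SimulationParams | None = None, **overrides
) -> tuple[CountMatrix, pd.DataFrame, ClassLabels]:
    """Draw a two-class count matrix plus its ground truth.

    Returns ``(counts, truth, labels)``: counts of shape
    ``(n_genes + spikein_count, 2 * n_per_class)`` with classes ``A``
    (control) then ``B``; a truth table aligned row-for-row with columns
    ``gene_id, true_logfc, is_de, is_spikein, subgroup``; and the matching
    :class:`ClassLabels`.  Fully deterministic given ``params.seed``.
    """
    if params is None:
        params = SimulationParams(**overrides)
    elif overrides:
        raise TypeError("pass either a SimulationParams or keyword overrides")
    rng = np.random.default_rng(params.seed)
    n, npc = params.n_genes, params.n_per_class
    L = 2 * npc

    lo, hi = params.base_mean_range
    q = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    logfc = np.zeros(n)
    n_de = int(round(params.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    if n_de:
        magnitudes = rng.choice(np.asarray(params.logfc_values, dtype=float), size=n_de)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        logfc[de_idx] = magnitudes * signs

    truth = pd.DataFrame(
        {
            "gene_id": [f"gene_{i:05d}" for i in range(n)],
            "true_logfc": logfc,
            "is_de": logfc != 0.0,
            "is_spikein": False,
            "subgroup": "none",
        }
    )
    if params.spikein_count:
        spike = spikein_panel(params)
        spike_q = np.exp(
            rng.uniform(np.log(lo), np.log(hi), size=params.spikein_count)
        )
        q = np.concatenate([q, spike_q])
        logfc = np.concatenate([logfc, spike["true_logfc"].to_numpy()])
        truth = pd.concat([truth, spike], ignore_index=True)

    slo, shi = params.size_factor_range
    sf = np.exp(rng.uniform(np.log(slo), np.log(shi), size=L))
    mean = sf[None, :] * q[:, None]
    mean[:, npc:] = mean[:, npc:] * 2.0 ** logfc[:, None]
    values = _nb_draw(rng, mean, params.dispersion)

    sample_ids = [f"A_{j+1}" for j in range(npc)] + [f"B_{j+1}" for j in range(npc)]
    counts = CountMatrix(values, list(truth["gene_id"]), sample_ids)
    labels = ClassLabels.from_sequence(["A"] * npc + ["B"] * npc, sample_ids)
    return counts, truth, labels
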
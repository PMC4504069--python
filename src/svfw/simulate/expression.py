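"""Expression-matrix simulation on a positive linear scale.

Every gene gets a per-gene baseline shared by all samples; genes tied to an
expression-affecting planted SV are scaled by the planted fold-change in the
carrier cancer samples only. Noise is multiplicative lognormal so the matrix
stays positive; noise_sd = 0 reproduces planted ratios exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..models import GeneModel, PlantedSV


@dataclass
class ExpressionConfig:
    n_controls: int = 8
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 0.6
    noise_sd: float = 0.0
    control_prefix: str = "N"

    def __post_init__(self):
        if self.n_controls < 2:
            raise ValueError("need at least two control samples")


def simulate_expression(
    truth: list[PlantedSV],
    models: list[GeneModel],
    patients: tuple[str, ...],
    config: ExpressionConfig,
    seed: int,
) -> pd.DataFrame:
    """Genes x (cancer + control) matrix; control columns named N01..N0k."""
    rng = np.random.default_rng(seed)
    genes = [m.gene_id for m in models]
    controls = [f"{config.control_prefix}{i + 1:02d}" for i in range(config.n_controls)]
    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, len(genes))
    )
    if np.any(baseline <= 0):
        raise ValueError("baseline must be positive")
    fold = pd.DataFrame(1.0, index=genes, columns=list(patients))
    for sv in truth:
        if sv.affected_gene and sv.expressed_change != 1.0 and sv.origin != "blood_only":
            for p in sv.samples:
                fold.loc[sv.affected_gene, p] = sv.expressed_change
    cols = {}
    for p in patients:
        noise = np.exp(rng.normal(0.0, config.noise_sd, len(genes))) if config.noise_sd else 1.0
        cols[p] = baseline * fold[p].to_numpy() * noise
    for c in controls:
        noise = np.exp(rng.normal(0.0, config.noise_sd, len(genes))) if config.noise_sd else 1.0
        cols[c] = baseline * noise
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
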
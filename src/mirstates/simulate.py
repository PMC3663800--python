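"""Synthetic paired miRNA/mRNA expression with planted differential regulation.

The generator emulates the situation the state pipeline is built for: a
collective of samples in a few clinical groups, a two-group contrast of
interest (e.g. normal vs tumor), and a catalog of putative miRNA-target
pairs of which some are genuinely differentially regulated. A planted pair
puts the miRNA at a high log level in one contrast class and a low level in
the other, with the target mRNA mirrored; decoy pairs sit at a single level.
Values are the level plus additive Gaussian noise on the log scale — the
minimal model matching the discretizer's own two-neighborhood assumption.
``flip_fraction`` flips individual samples of a planted pair to the opposite
regulation, modelling per-sample biological heterogeneity (outlier samples);
at 0.5 a planted pair is indistinguishable from group-independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import ExpressionMatrix, GroupAssignment


@dataclass
class SimulationParams:
    """Generative parameters; defaults mirror a 24-sample three-group
    collective (8 control + 2x8 tumor) with a normal-vs-tumor contrast."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"normal": 8, "noninvasive": 8, "invasive": 8}
    )
    contrast: dict[str, str] = field(
        default_factory=lambda: {"normal": "normal", "noninvasive": "tumor", "invasive": "tumor"}
    )
    n_planted: int = 50
    n_decoys: int = 450
    log_fold: float = 2.0  # separation between the two log levels (e^2-fold)
    noise_sd: float = 0.2  # within-state sd on the log scale
    planted_anticorrelation: float = 0.8  # within-group miRNA/target noise coupling
    flip_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 samples")
        if self.log_fold <= 0:
            raise ValueError("log_fold must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.flip_fraction <= 1.0:
            raise ValueError("flip_fraction must lie in [0, 1]")
        if not 0.0 <= self.planted_anticorrelation <= 1.0:
            raise ValueError("planted_anticorrelation must lie in [0, 1]")
        if set(self.contrast) != set(self.group_sizes):
            raise ValueError("contrast must label exactly the groups in group_sizes")
        if len(set(self.contrast.values())) != 2:
            raise ValueError("contrast must define exactly two classes")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    planted: list[tuple[str, str]]
    planted_direction: dict[tuple[str, str], str]  # 'down_in_A': mRNA down in class A
    decoys: list[tuple[str, str]]
    clinical_groups: GroupAssignment  # fine-grained groups
    contrast_classes: tuple[str, str]  # (class A, class B)
    params: SimulationParams


def generate_dataset(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.Series, list[tuple[str, str]], GroupAssignment, SyntheticTruth]:
    """Generate (miRNA matrix, mRNA matrix, probe->gene map, catalog,
    contrast groups, truth); fully determined by ``params.seed``."""
    rng = np.random.default_rng(params.seed)

    sample_ids: list[str] = []
    clinical: list[str] = []
    for g, n in params.group_sizes.items():
        for i in range(n):
            sample_ids.append(f"{g}_{i + 1}")
            clinical.append(g)
    binary = [params.contrast[g] for g in clinical]
    classes = list(dict.fromkeys(params.contrast.values()))
    class_a = classes[0]
    in_a = np.array([b == class_a for b in binary])
    m = len(sample_ids)

    n_pairs = params.n_planted + params.n_decoys
    mirna_ids = [f"mir-{i + 1}" for i in range(n_pairs)]
    gene_ids = [f"gene{i + 1}" for i in range(n_pairs)]
    probe_ids = [f"probe{i + 1}" for i in range(n_pairs)]

    lo, hi = 0.0, params.log_fold
    mirna_rows = np.empty((n_pairs, m))
    mrna_rows = np.empty((n_pairs, m))
    planted: list[tuple[str, str]] = []
    directions: dict[tuple[str, str], str] = {}
    decoys: list[tuple[str, str]] = []

    for i in range(n_pairs):
        pair = (mirna_ids[i], gene_ids[i])
        if i < params.n_planted:
            # mirna up in class A for even i, up in class B for odd i
            mir_high_in_a = i % 2 == 0
            mir_high = in_a if mir_high_in_a else ~in_a
            if params.flip_fraction > 0:
                flips = rng.random(m) < params.flip_fraction
                mir_high = np.where(flips, ~mir_high, mir_high)
            mirna_rows[i] = np.where(mir_high, hi, lo)
            mrna_rows[i] = np.where(mir_high, lo, hi)
            planted.append(pair)
            directions[pair] = "down_in_A" if mir_high_in_a else "up_in_A"
        else:
            mirna_rows[i] = lo
            mrna_rows[i] = lo
            decoys.append(pair)

    if params.noise_sd > 0:
        # Planted targets get noise anti-correlated with their miRNA's noise
        # (within-group trace of repression); marginal sd stays noise_sd.
        eps_mir = rng.normal(0.0, params.noise_sd, size=mirna_rows.shape)
        eps_ind = rng.normal(0.0, params.noise_sd, size=mrna_rows.shape)
        rho = params.planted_anticorrelation
        mirna_rows += eps_mir
        mrna_rows += eps_ind
        if params.n_planted and rho > 0:
            sl = slice(0, params.n_planted)
            mrna_rows[sl] += -rho * eps_mir[sl] + (np.sqrt(1 - rho**2) - 1.0) * eps_ind[sl]

    mirna = ExpressionMatrix(
        pd.DataFrame(mirna_rows, index=mirna_ids, columns=sample_ids), "miRNA"
    )
    mrna = ExpressionMatrix(
        pd.DataFrame(mrna_rows, index=probe_ids, columns=sample_ids), "mRNA"
    )
    probe_gene_map = pd.Series(gene_ids, index=probe_ids, name="gene_id")
    catalog = planted + decoys
    groups = GroupAssignment(pd.Series(binary, index=sample_ids))
    truth = SyntheticTruth(
        planted=planted,
        planted_direction=directions,
        decoys=decoys,
        clinical_groups=GroupAssignment(pd.Series(clinical, index=sample_ids)),
        contrast_classes=(classes[0], classes[1]),
        params=params,
    )
    return mirna, mrna, probe_gene_map, catalog, groups, truth
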
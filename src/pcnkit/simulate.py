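"""Synthetic inputs with the statistical structure the pipeline assumes.

Emulates a single-channel microarray study: a vehicle control plus several
dose groups, a handful of biological replicates each, with a dose-increasing
number of genes planted as truly differentially expressed.  Also generates
pathway databases with controlled pairwise overlaps and cross-species
symbol-mapping tables, so every downstream stage is testable without any
external data.

Noise model: per-probe baseline log2 intensities drawn uniformly from a
stated range, Gaussian noise on the log2 scale, exponentiated to the
intensity scale.  Planted genes receive a mean shift of ``effect_size`` on
the log2 scale (sign chosen per gene) in the affected dose groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ABSENT, PRESENT, ExpressionMatrix
from .pathways import GeneMapping, Pathway, PathwayDB

CONTROL_LABEL = "control"


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a simulated experiment.

    Attributes
    ----------
    planted_deg_ids : dict[str, frozenset[str]]
        Per dose label, the set of gene ids planted as differentially
        expressed relative to control.
    effect_size : dict[str, float]
        Signed log2-scale mean shift per planted gene (constant across the
        doses in which the gene is planted).
    noise_sd : float
        Standard deviation of the log2-scale noise.
    seed : int
    """

    planted_deg_ids: dict[str, frozenset]
    effect_size: dict[str, float]
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        for gene, eff in self.effect_size.items():
            if not np.isfinite(eff) or eff == 0.0:
                raise ValueError(f"effect size for planted gene {gene} must be finite and nonzero")


def simulate_expression(
    n_probes: int,
    dose_levels: list[str],
    n_replicates: int = 4,
    deg_fraction_per_dose: tuple[float, ...] = (0.01, 0.05, 0.15),
    effect_size: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    *,
    baseline_log2_range: tuple[float, float] = (6.0, 12.0),
    absent_rate: float = 0.05,
    monotone: bool = True,
    up_fraction: float = 0.5,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate a control + multi-dose expression matrix with planted DEGs.

    Parameters
    ----------
    n_probes : int
        Number of probes (one gene per probe).
    dose_levels : list of str
        Dose group labels, low to high, excluding the control (a
        ``"control"`` group is always generated).
    n_replicates : int
        Biological replicates per group (≥ 2).
    deg_fraction_per_dose : tuple of float
        Fraction of probes planted as DEGs at each dose; one entry per
        dose level.  With ``monotone=True`` the planted sets are nested
        (every lower-dose DEG is also a DEG at higher doses), so fractions
        must be non-decreasing.
    effect_size : float
        Magnitude of the planted log2 mean shift.  ``0`` plants nothing.
    noise_sd : float
        Log2-scale Gaussian noise SD.
    seed : int
        Seeds all randomness; identical arguments + seed give bit-identical
        output.
    absent_rate : float
        Independent probability that any (probe, sample) entry is flagged
        absent.
    monotone : bool
        Nest planted sets across doses.  ``False`` draws each dose's
        planted set independently.
    up_fraction : float
        Expected fraction of planted genes shifted upward.

    Returns
    -------
    (ExpressionMatrix, SimulationTruth)
    """
    if n_probes <= 0 or n_replicates <= 0:
        raise ValueError("n_probes and n_replicates must be positive")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per group")
    if len(deg_fraction_per_dose) != len(dose_levels):
        raise ValueError("one DEG fraction per dose level required")
    for f in deg_fraction_per_dose:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"deg_fraction {f} outside [0, 1]")
    if monotone and any(
        b < a for a, b in zip(deg_fraction_per_dose, deg_fraction_per_dose[1:])
    ):
        raise ValueError("monotone design requires non-decreasing deg fractions")
    if not 0.0 <= absent_rate <= 1.0:
        raise ValueError("absent_rate outside [0, 1]")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")

    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:05d}" for i in range(n_probes)])
    groups = [CONTROL_LABEL] + list(dose_levels)
    sample_ids, dose_of = [], []
    for g in groups:
        for r in range(1, n_replicates + 1):
            sample_ids.append(f"{g}_r{r}")
            dose_of.append(g)

    baseline = rng.uniform(*baseline_log2_range, size=n_probes)

    # Planted sets: nested for the monotone design, independent otherwise.
    planted: dict[str, frozenset] = {}
    effects: dict[str, float] = {}
    if effect_size != 0.0:
        if monotone:
            order = rng.permutation(n_probes)
            for dose, frac in zip(dose_levels, deg_fraction_per_dose):
                k = int(round(frac * n_probes))
                planted[dose] = frozenset(genes[order[:k]])
        else:
            for dose, frac in zip(dose_levels, deg_fraction_per_dose):
                k = int(round(frac * n_probes))
                idx = rng.choice(n_probes, size=k, replace=False)
                planted[dose] = frozenset(genes[idx])
        all_planted = sorted(set().union(*planted.values())) if planted else []
        signs = np.where(rng.random(len(all_planted)) < up_fraction, 1.0, -1.0)
        effects = {g: float(s * effect_size) for g, s in zip(all_planted, signs)}
    else:
        planted = {dose: frozenset() for dose in dose_levels}

    gene_pos = {g: i for i, g in enumerate(genes)}
    log2_means = np.tile(baseline[:, None], (1, len(sample_ids)))
    for j, dose in enumerate(dose_of):
        if dose == CONTROL_LABEL:
            continue
        for g in planted.get(dose, ()):  # shift treated means only
            log2_means[gene_pos[g], j] += effects[g]

    log2_vals = log2_means + rng.normal(0.0, noise_sd, size=log2_means.shape)
    intens = pd.DataFrame(
        np.exp2(log2_vals), index=pd.Index(genes, name="probe_id"), columns=sample_ids
    )
    flag_vals = np.where(rng.random(intens.shape) < absent_rate, ABSENT, PRESENT)
    flags = pd.DataFrame(flag_vals, index=intens.index, columns=intens.columns)
    dose_group = pd.Series(dose_of, index=pd.Index(sample_ids, name="sample_id"))

    truth = SimulationTruth(
        planted_deg_ids=planted, effect_size=effects, noise_sd=noise_sd, seed=seed
    )
    matrix = ExpressionMatrix(intens, flags, dose_group, scale_state="raw")
    return matrix, truth


def simulate_pathway_db(
    n_pathways: int,
    size_range: tuple[int, int] = (10, 40),
    overlap_spec: dict[tuple[int, int], int] | None = None,
    universe_size: int = 2000,
    seed: int = 0,
    *,
    gene_ids: list[str] | None = None,
) -> PathwayDB:
    """Generate a pathway database with exact requested pairwise overlaps.

    Each requested pair ``(i, j) -> k`` shares exactly ``k`` members; shared
    blocks are pair-private and all remaining members are unique to one
    pathway, so unrequested pairs are disjoint.  Triple intersections are
    therefore always empty — requested overlaps must fit within the pathway
    sizes (sum of a pathway's overlaps ≤ its size).

    Parameters
    ----------
    n_pathways : int
        Number of gene sets, named ``PW000 ...``.
    size_range : (int, int)
        Inclusive bounds for pathway sizes (drawn uniformly).
    overlap_spec : dict mapping (i, j) index pairs to shared-member counts.
    universe_size : int
        Size of the symbol universe to draw members from.
    gene_ids : optional list of str
        Explicit universe (overrides ``universe_size``); lets callers reuse
        the expression simulator's gene ids so DEGs land inside pathways.
    """
    if n_pathways <= 0:
        raise ValueError("n_pathways must be positive")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid size_range")
    overlap_spec = dict(overlap_spec or {})

    rng = np.random.default_rng(seed)
    if gene_ids is None:
        universe = np.array([f"G{i:05d}" for i in range(universe_size)])
    else:
        universe = np.array(sorted(set(gene_ids)))
    sizes = rng.integers(lo, hi + 1, size=n_pathways)

    # feasibility: each pathway must accommodate the sum of its overlaps
    norm_spec: dict[tuple[int, int], int] = {}
    for (i, j), k in overlap_spec.items():
        if i == j or not (0 <= i < n_pathways and 0 <= j < n_pathways):
            raise ValueError(f"invalid pathway pair {(i, j)}")
        if k < 0:
            raise ValueError(f"negative overlap for pair {(i, j)}")
        norm_spec[(min(i, j), max(i, j))] = k
    demand = np.zeros(n_pathways, dtype=int)
    for (i, j), k in norm_spec.items():
        if k > min(sizes[i], sizes[j]):
            raise ValueError(
                f"infeasible overlap_spec: pair {(i, j)} requests {k} shared members "
                f"but sizes are ({sizes[i]}, {sizes[j]})"
            )
        demand[i] += k
        demand[j] += k
    for i in range(n_pathways):
        if demand[i] > sizes[i]:
            pairs = [p for p in norm_spec if i in p]
            raise ValueError(
                f"infeasible overlap_spec: pathway {i} (size {sizes[i]}) cannot hold "
                f"{demand[i]} shared members across pairs {pairs}"
            )
    total_needed = sum(norm_spec.values()) + int(np.sum(sizes) - np.sum(demand))
    if total_needed > len(universe):
        raise ValueError(
            f"universe of {len(universe)} symbols too small for {total_needed} distinct members"
        )

    pool = list(rng.permutation(universe))
    members: list[set] = [set() for _ in range(n_pathways)]
    for (i, j), k in sorted(norm_spec.items()):
        shared = [pool.pop() for _ in range(k)]
        members[i].update(shared)
        members[j].update(shared)
    for i in range(n_pathways):
        while len(members[i]) < sizes[i]:
            members[i].add(pool.pop())

    pathways = [
        Pathway(
            pathway_id=f"PW{i:03d}",
            name=f"PW{i:03d}",
            source="synthetic",
            members=frozenset(str(m).upper() for m in members[i]),
        )
        for i in range(n_pathways)
    ]
    return PathwayDB(pathways)


def simulate_ortholog_map(
    source_ids: list[str],
    target_universe: list[str],
    unmapped_fraction: float = 0.0,
    one_to_many_fraction: float = 0.0,
    seed: int = 0,
    *,
    max_targets: int = 2,
) -> pd.DataFrame:
    """Simulate a cross-species symbol mapping table.

    Returns a two-column DataFrame (``source``, ``target``), one pair per
    row; repeated sources encode one-to-many mappings.  The stated fractions
    of source ids (rounded to counts) get zero / multiple targets, the rest
    map one-to-one.
    """
    for f in (unmapped_fraction, one_to_many_fraction):
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    if unmapped_fraction + one_to_many_fraction > 1.0:
        raise ValueError("unmapped + one-to-many fractions exceed 1")
    if not target_universe and unmapped_fraction < 1.0 and source_ids:
        raise ValueError("empty target_universe but mapping requested")

    rng = np.random.default_rng(seed)
    n = len(source_ids)
    n_unmapped = int(round(unmapped_fraction * n))
    n_multi = int(round(one_to_many_fraction * n))
    order = rng.permutation(n)
    unmapped = {source_ids[i] for i in order[:n_unmapped]}
    multi = {source_ids[i] for i in order[n_unmapped : n_unmapped + n_multi]}

    targets = [str(t).upper() for t in target_universe]
    rows = []
    for s in source_ids:
        if s in unmapped:
            continue
        k = max_targets if s in multi else 1
        chosen = rng.choice(len(targets), size=min(k, len(targets)), replace=False)
        for c in chosen:
            rows.append((s, targets[c]))
    return pd.DataFrame(rows, columns=["source", "target"])


def identity_mapping(ids) -> GeneMapping:
    """Mapping that sends every id to its own uppercased symbol."""
    return GeneMapping({str(i): frozenset({str(i).upper()}) for i in ids})


def write_mapping(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a two-column mapping table as tab-separated text (no header)."""
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, header=False)
    return path
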
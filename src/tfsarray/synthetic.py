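"""Synthetic dye-swap two-color microarray experiments with known truth.

The generator emulates the four-comparison competitive design used to
dissect a two-treatment (testosterone x MAA) response: per comparison, RNA
from pooled biological replicates is hybridized in both dye orientations
(reverse-pair / dye-swap), so with the default two pools each comparison
yields four arrays.  Per-gene ground truth is *planted* as a 4-tuple of
direction calls in {0,1,2} with a target |log2 effect|, which fixes the TFS
code and interaction class each gene should receive downstream.

Signal model per feature and channel:

    I = 2^(baseline + effect + dye_bias) * exp(N(0, sigma_mult)) + N(0, sigma_add)

with intensities clipped at zero.  The dye bias is a smooth low-order
polynomial of the noiseless mean log2 intensity applied to channel A only
(the bias travels with the dye, not the sample), which is exactly the kind
of trend LOWESS normalization removes and dye-swap averaging cancels.
Features are randomly flagged saturated-in-both-channels (intensities forced
to the saturation ceiling) or non-uniform (intensities corrupted), so the
exclusion rules have work to do.  Redundant probes share their gene's
planted effects but draw independent noise, exercising the same-pattern
collapse rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .tfs import CLASS_TABLE, TfsCode, assign_class, compute_tfs

SATURATION_CEILING = 65535.0

#: planted pattern: four direction calls plus target |log2 effect|
Pattern = tuple[tuple[int, int, int, int], float]


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one simulated dye-swap experiment.

    ``planted_patterns`` maps gene_id -> ((d1,d2,d3,d4), |log2 effect|); all
    unlisted genes are null.  ``n_redundant_genes`` genes (sampled from all
    genes) carry two probes with identical planted effects.  With
    ``dye_swap`` each pool is measured in both dye orientations, so each of
    the four comparisons has ``n_pools * 2`` hybridizations.
    """

    n_genes: int = 2000
    n_redundant_genes: int = 100
    n_unannotated_probes: int = 20
    planted_patterns: Mapping[str, Pattern] = field(default_factory=dict)
    n_pools: int = 2
    dye_swap: bool = True
    baseline_loc: float = 10.0       # log2 intensity units
    baseline_scale: float = 1.5
    sigma_add: float = 30.0          # intensity units
    sigma_mult: float = 0.15         # natural-log scale
    dye_bias_amplitude: float = 0.3  # log2 units
    rate_saturated_both: float = 0.005
    rate_nonuniform: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.n_genes <= 0:
            errors.append(f"n_genes must be positive, got {self.n_genes}")
        if not 0 <= self.n_redundant_genes <= self.n_genes:
            errors.append("n_redundant_genes must be in [0, n_genes]")
        if self.n_unannotated_probes < 0:
            errors.append("n_unannotated_probes must be >= 0")
        if self.n_pools < 1:
            errors.append(f"n_pools must be >= 1, got {self.n_pools}")
        if self.baseline_scale < 0 or self.sigma_add < 0 or self.sigma_mult < 0:
            errors.append("scale/noise parameters must be non-negative")
        for rate_name in ("rate_saturated_both", "rate_nonuniform"):
            r = getattr(self, rate_name)
            if not 0 <= r <= 1:
                errors.append(f"{rate_name} must be in [0, 1], got {r}")
        for gene, (calls, effect) in self.planted_patterns.items():
            if len(calls) != 4 or any(c not in (0, 1, 2) for c in calls):
                errors.append(f"{gene}: calls must be four values in {{0,1,2}}")
            elif any(c != 0 for c in calls):
                if effect <= 0:
                    errors.append(f"{gene}: planted magnitude must be > 0")
                elif effect <= 1.0:
                    warnings.warn(
                        f"{gene}: planted |log2 effect| {effect} <= 1; "
                        "below the 2-fold call threshold",
                        stacklevel=2,
                    )
        if errors:
            raise ValueError("invalid design: " + "; ".join(errors))


class SimulatedExperiment(NamedTuple):
    """Hybridization tables per comparison, ground truth, probe annotation."""

    hybridizations: dict[int, list[pd.DataFrame]]
    truth: pd.DataFrame
    annotation: pd.DataFrame


def gene_ids(n_genes: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n_genes)]


def random_planted_patterns(
    n_genes: int,
    n_planted: int,
    effect: float = 2.0,
    seed: int = 0,
    codes: list[str] | None = None,
) -> dict[str, Pattern]:
    """Plant ``n_planted`` genes uniformly across a set of TFS codes.

    By default the 27 named interaction codes plus two unnamed ("other")
    patterns are used, so every downstream class — including "other" — has
    representatives.
    """
    if codes is None:
        codes = list(CLASS_TABLE) + ["7.1110", "11.2202"]
    rng = np.random.default_rng(seed)
    genes = gene_ids(n_genes)
    chosen = rng.choice(n_genes, size=n_planted, replace=False)
    out: dict[str, Pattern] = {}
    for idx in sorted(chosen):
        code = TfsCode.from_text(codes[int(rng.integers(len(codes)))])
        out[genes[idx]] = (code.digits, effect)
    return out


def default_design(
    n_genes: int = 2000,
    n_planted: int = 300,
    effect: float = 2.0,
    seed: int = 0,
    **overrides,
) -> SimulationDesign:
    """The standard study-scale design: 2000 genes, 15% planted, 4-fold effects."""
    patterns = random_planted_patterns(n_genes, n_planted, effect=effect, seed=seed)
    return SimulationDesign(
        n_genes=n_genes, planted_patterns=patterns, seed=seed, **overrides
    )


def null_design(n_genes: int = 6416, seed: int = 0, **overrides) -> SimulationDesign:
    """A fully null design (no planted effects) for calibration checks."""
    return SimulationDesign(
        n_genes=n_genes,
        n_redundant_genes=0,
        n_unannotated_probes=0,
        planted_patterns={},
        seed=seed,
        **overrides,
    )


def _dye_bias(a0: np.ndarray, design: SimulationDesign) -> np.ndarray:
    """Smooth low-order polynomial bias in log2 units, bounded by the amplitude."""
    z = (a0 - design.baseline_loc) / (3.0 * max(design.baseline_scale, 1e-9))
    z = np.clip(z, -1.5, 1.5)
    return design.dye_bias_amplitude * (0.8 * z**2 - 0.6 * z)


def simulate_experiment(design: SimulationDesign) -> SimulatedExperiment:
    """Simulate the full four-comparison dye-swap experiment.

    Returns hybridization tables (one list per comparison, ``n_pools * 2``
    arrays each under dye swap), the gene-level truth table (gene_id,
    call_1..4, tfs, tfs_class), and the probe annotation.  Identical designs
    (including seed) give bit-identical output.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    genes = gene_ids(design.n_genes)
    redundant = set(
        np.array(genes)[
            rng.choice(design.n_genes, size=design.n_redundant_genes, replace=False)
        ]
    )
    probe_gene: list[tuple[str, str]] = []
    for g in genes:
        probe_gene.append((f"p_{g}_a", g))
        if g in redundant:
            probe_gene.append((f"p_{g}_b", g))
    for i in range(design.n_unannotated_probes):
        probe_gene.append((f"p_unk{i:04d}", ""))
    probe_gene.sort()
    probes = np.array([p for p, _ in probe_gene])
    probe_genes = np.array([g for _, g in probe_gene])
    n_probes = len(probes)

    # per-probe baseline abundance; per-gene planted effects (log2)
    baseline = rng.normal(design.baseline_loc, design.baseline_scale, size=n_probes)
    effect = np.zeros((n_probes, 4))
    for gene, (calls, mag) in design.planted_patterns.items():
        mask = probe_genes == gene
        if not mask.any():
            raise ValueError(f"planted gene {gene!r} not in the simulated gene set")
        for k, c in enumerate(calls):
            if c == 1:
                effect[mask, k] = mag
            elif c == 2:
                effect[mask, k] = -mag

    orientations = ("forward", "reverse") if design.dye_swap else ("forward",)
    hybridizations: dict[int, list[pd.DataFrame]] = {}
    for comp in range(1, 5):
        treat = baseline + effect[:, comp - 1]
        ref = baseline
        a0 = 0.5 * (treat + ref)
        bias = _dye_bias(a0, design)
        tables = []
        for _pool in range(design.n_pools):
            for orientation in orientations:
                # channel A carries the first dye (and its bias) in both
                # orientations; the treatment sample sits in A only on
                # forward arrays
                xa = (treat if orientation == "forward" else ref) + bias
                xb = ref if orientation == "forward" else treat
                ia = np.exp2(xa) * np.exp(
                    rng.normal(0.0, design.sigma_mult, n_probes)
                ) + rng.normal(0.0, design.sigma_add, n_probes)
                ib = np.exp2(xb) * np.exp(
                    rng.normal(0.0, design.sigma_mult, n_probes)
                ) + rng.normal(0.0, design.sigma_add, n_probes)
                ia, ib = np.clip(ia, 0.0, None), np.clip(ib, 0.0, None)

                sat = rng.random(n_probes) < design.rate_saturated_both
                ia[sat] = ib[sat] = SATURATION_CEILING
                nonuni = rng.random(n_probes) < design.rate_nonuniform
                nu_channel = rng.random(n_probes) < 0.5
                nu_a = nonuni & nu_channel
                nu_b = nonuni & ~nu_channel
                corrupt = rng.uniform(0.2, 5.0, n_probes)
                ia[nu_a] *= corrupt[nu_a]
                ib[nu_b] *= corrupt[nu_b]

                tables.append(
                    pd.DataFrame(
                        {
                            "probe_id": probes,
                            "gene_id": probe_genes,
                            "channel_A_intensity": ia,
                            "channel_B_intensity": ib,
                            "dye_orientation": orientation,
                            "flag_saturated_A": sat,
                            "flag_saturated_B": sat,
                            "flag_nonuniform_A": nu_a,
                            "flag_nonuniform_B": nu_b,
                        }
                    )
                )
        hybridizations[comp] = tables

    truth = build_truth(genes, design.planted_patterns)
    annotation = pd.DataFrame({"probe_id": probes, "gene_id": probe_genes})
    return SimulatedExperiment(hybridizations, truth, annotation)


def build_truth(
    genes: list[str], planted: Mapping[str, Pattern]
) -> pd.DataFrame:
    """Gene-level truth table; TFS codes and classes via the classifier itself."""
    rows = []
    for g in genes:
        calls = planted[g][0] if g in planted else (0, 0, 0, 0)
        code = compute_tfs(calls)
        rows.append(
            {
                "gene_id": g,
                "call_1": calls[0],
                "call_2": calls[1],
                "call_3": calls[2],
                "call_4": calls[3],
                "tfs": code.text,
                "tfs_class": assign_class(code).label,
            }
        )
    return pd.DataFrame(rows)


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write a truth table as TSV (lossless round-trip with :func:`read_truth`)."""
    if truth is None or len(truth) == 0:
        raise ValueError("refusing to write an empty truth table")
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene_id": str, "tfs": str, "tfs_class": str},
    )
    return df


def fixture_collections(
    truth: pd.DataFrame,
    seed: int = 0,
    n_decoys: int = 20,
    decoy_size: int = 50,
    planted_size: int = 40,
    n_background: int = 10,
):
    """Build GMT-style gene-set collections with one set planted per TFS group.

    For every non-null TFS group in ``truth`` with at least 5 genes, a set
    named ``PLANTED_<code>`` is built from up to ``planted_size`` of that
    group's true genes plus ``n_background`` random genes; ``n_decoys``
    random sets of ``decoy_size`` genes are added.  Returns a list of
    :class:`tfsarray.io.GeneSet`.
    """
    from .io import GeneSet

    rng = np.random.default_rng(seed)
    universe = truth["gene_id"].tolist()
    sets = []
    grouped = truth[truth["tfs"] != "0.0000"].groupby("tfs", sort=True)
    for code, sub in grouped:
        members = sub["gene_id"].tolist()
        if len(members) < 5:
            continue
        take = min(planted_size, len(members))
        chosen = list(rng.choice(members, size=take, replace=False))
        background = list(rng.choice(universe, size=n_background, replace=False))
        sets.append(
            GeneSet(
                name=f"PLANTED_{code.replace('.', '_')}",
                description=f"genes planted in TFS group {code}",
                members=frozenset(chosen) | frozenset(background),
            )
        )
    for i in range(n_decoys):
        sets.append(
            GeneSet(
                name=f"DECOY_{i:03d}",
                description="random background set",
                members=frozenset(rng.choice(universe, size=decoy_size, replace=False)),
            )
        )
    return sets
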
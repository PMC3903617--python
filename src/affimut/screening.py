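"""In-silico saturation mutagenesis screen.

For every selected CDR position, each of the other 19 natural amino acids
is modeled as a randomized relaxed ensemble and scored by the cross-partner
nonbonded energy.  Models without any antigen contact are discarded.  Each
mutation's ensemble median is compared with a wild-type reference ensemble
median; negative shifts (delta-E) suggest higher affinity.

Per-mutation random streams are derived from the master seed and a stable
hash of the mutation id, so the report is byte-identical regardless of
execution order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .energy import ForceFieldParams
from .mutate import (MinimizationConfig, ModelEnsemble, MutationSpec,
                     RotamerLibrary, build_ensemble, movable_selection_around)
from .structure import (AA3_TO_1, STANDARD_AA3, CdrSelection, ComplexStructure,
                        StructureError, interface_residues)


@dataclass
class ScreeningConfig:
    """Screen-wide settings.

    ``delta_e_threshold`` (kcal/mol) and ``min_valid_fraction`` concretize
    the selection rule: a mutation is selected when its median shift is at
    or below the threshold and enough models survive the contact filter.
    """

    n_models_per_mutation: int = 100
    n_wt_models: int = 1000
    contact_cutoff: float = 4.5
    delta_e_threshold: float = -1.0
    min_valid_fraction: float = 0.5
    master_seed: int = 0
    statistic: str = "median"  # or "mean"
    #: "global" relaxes every rotatable side chain near the interface (both
    #: partners, fixed set) in WT and mutant models alike, so delta-E is not
    #: biased by asymmetric movable sets; "local" restricts mutant models to
    #: the 6 A neighborhood of the mutated side chain.
    movable_policy: str = "global"
    #: residues whose heavy atoms come within this distance of the other
    #: partner belong to the relaxing interface zone (global policy), A
    interface_zone: float = 8.0
    minimization: MinimizationConfig = field(default_factory=MinimizationConfig)

    def __post_init__(self) -> None:
        if self.n_models_per_mutation < 2:
            raise ValueError("n_models_per_mutation must be >= 2")
        if not np.isfinite(self.delta_e_threshold):
            raise ValueError("delta_e_threshold must be finite")


@dataclass
class EnergyHistogram:
    """Binned ensemble energies plus summary statistics."""

    bin_edges: np.ndarray
    counts: np.ndarray
    median: float
    mean: float
    iqr: float

    @classmethod
    def from_energies(cls, energies, n_bins: int = 20) -> "EnergyHistogram":
        e = np.asarray(sorted(energies), dtype=float)
        counts, edges = np.histogram(e, bins=n_bins)
        q1, q3 = np.percentile(e, [25, 75])
        return cls(edges, counts, float(np.median(e)), float(e.mean()),
                   float(q3 - q1))


@dataclass
class MutationResult:
    """One substitution's screened outcome."""

    mutation_id: str
    chain_id: str
    number: int
    wt_aa: str
    mut_aa: str
    energies: list[float]
    n_filtered: int
    median: float
    mean: float
    delta_e: float
    delta_e_mean: float
    selected: bool
    no_contact: bool = False
    n_converged: int = 0
    n_models: int = 0
    #: non-empty when the mutation could not be modeled (e.g. Pro target)
    failure: str = ""

    @property
    def excluded(self) -> bool:
        return self.no_contact or bool(self.failure)


def mutation_seed(master_seed: int, mutation_id: str) -> np.random.SeedSequence:
    """Stable per-mutation seed stream (independent of execution order)."""
    return np.random.SeedSequence([master_seed, zlib.crc32(mutation_id.encode())])


def enumerate_library(structure: ComplexStructure,
                      selection: CdrSelection) -> list[MutationSpec]:
    """All-but-wild-type substitutions: exactly 19 specs per position.

    Deterministic order: positions in the given order, targets
    alphabetical by 3-letter code.
    """
    if not selection.residues:
        raise StructureError("empty CDR selection")
    seen = set()
    specs: list[MutationSpec] = []
    for cid, num in selection.residues:
        if (cid, num) in seen:
            raise StructureError(f"duplicate position {cid}{num}")
        seen.add((cid, num))
        wt = structure.get_residue(cid, num).name
        if wt not in STANDARD_AA3:
            raise StructureError(f"unknown wild-type identity {wt} at {cid}{num}")
        for target in sorted(STANDARD_AA3):
            if target == wt:
                continue
            specs.append(MutationSpec(cid, num, target, "sample"))
    return specs


def movable_keys_for(structure: ComplexStructure,
                     config: ScreeningConfig) -> list[tuple[str, int]]:
    """Residues whose side chains relax during model generation."""
    from .mutate import N_CHI
    if config.movable_policy == "global":
        zone = {(r.chain_id, r.number)
                for pair in interface_residues(structure, config.interface_zone)
                for r in pair}
        keys = sorted((r.chain_id, r.number) for r in structure.residues()
                      if N_CHI.get(r.name, 0) > 0
                      and (r.chain_id, r.number) in zone)
    else:
        pairs = interface_residues(structure, config.contact_cutoff)
        keys = sorted({(r.chain_id, r.number) for pair in pairs for r in pair
                       if N_CHI.get(r.name, 0) > 0})
    return keys


def wt_reference(
    structure: ComplexStructure,
    config: ScreeningConfig,
    library: RotamerLibrary | None = None,
    params: ForceFieldParams | None = None,
) -> tuple[EnergyHistogram, float, ModelEnsemble]:
    """Wild-type reference ensemble: perturb + relax the movable side chains.

    Returns the energy histogram, the reference statistic (median by
    default) and the raw ensemble.
    """
    keys = movable_keys_for(structure, config)
    if not keys:
        # rigid interface: zero-width distribution at the static energy
        from .energy import interaction_energy
        e = interaction_energy(structure, config.minimization.energy_config).e_total
        hist = EnergyHistogram.from_energies([e, e])
        ens = ModelEnsemble("WT", [], int(mutation_seed(config.master_seed, "WT")
                                          .generate_state(1)[0]))
        return hist, e, ens
    seed = int(mutation_seed(config.master_seed, "WT").generate_state(1)[0] % (2**31))
    ensemble = build_ensemble(
        structure, None, config.n_wt_models, config.minimization,
        seed=seed, library=library, params=params, movable_keys=keys)
    energies = ensemble.energies()
    hist = EnergyHistogram.from_energies(energies)
    stat = hist.median if config.statistic == "median" else hist.mean
    return hist, stat, ensemble


def filter_no_contact(ensemble: ModelEnsemble,
                      cutoff: float = 4.5) -> tuple[list[float], int]:
    """Drop models without any cross-partner heavy-atom pair within cutoff.

    Returns the surviving energies and the number filtered out.
    """
    kept, dropped = [], 0
    for m in ensemble.models:
        if m.energy is None:
            dropped += 1
            continue
        if m.min_cross_distance <= cutoff:
            kept.append(m.energy.e_total)
        else:
            dropped += 1
    return kept, dropped


def delta_energy(energies, wt_stat: float, statistic: str = "median") -> float:
    """Median (or mean) ensemble shift vs the wild-type reference, kcal/mol."""
    if len(energies) == 0:
        raise ValueError("no valid models")
    agg = np.median if statistic == "median" else np.mean
    return float(agg(np.asarray(energies)) - wt_stat)


def screen_mutation(
    structure: ComplexStructure,
    spec: MutationSpec,
    wt_median: float,
    wt_mean: float,
    config: ScreeningConfig,
    library: RotamerLibrary | None = None,
    params: ForceFieldParams | None = None,
) -> MutationResult:
    """Build, filter and score one mutation's ensemble."""
    wt3 = structure.get_residue(spec.chain_id, spec.number).name
    mid = spec.mutation_id(wt3)
    seed = int(mutation_seed(config.master_seed, mid).generate_state(1)[0] % (2**31))
    movable = None
    if config.movable_policy == "global":
        movable = sorted(set(movable_keys_for(structure, config))
                         | {(spec.chain_id, spec.number)})
    try:
        ensemble = build_ensemble(
            structure, spec, config.n_models_per_mutation, config.minimization,
            seed=seed, library=library, params=params, movable_keys=movable)
    except (StructureError, RuntimeError) as exc:
        return MutationResult(
            mutation_id=mid, chain_id=spec.chain_id, number=spec.number,
            wt_aa=AA3_TO_1[wt3], mut_aa=AA3_TO_1[spec.target3],
            energies=[], n_filtered=0, median=np.nan, mean=np.nan,
            delta_e=np.nan, delta_e_mean=np.nan, selected=False,
            failure=str(exc))
    energies, n_filtered = filter_no_contact(ensemble, config.contact_cutoff)
    n_models = len(ensemble.models)
    if not energies:
        return MutationResult(
            mutation_id=mid, chain_id=spec.chain_id, number=spec.number,
            wt_aa=AA3_TO_1[wt3], mut_aa=AA3_TO_1[spec.target3],
            energies=[], n_filtered=n_filtered, median=np.nan, mean=np.nan,
            delta_e=np.nan, delta_e_mean=np.nan, selected=False,
            no_contact=True, n_converged=ensemble.n_converged(),
            n_models=n_models)
    de_med = delta_energy(energies, wt_median, "median")
    de_mean = delta_energy(energies, wt_mean, "mean")
    de = de_med if config.statistic == "median" else de_mean
    valid_frac = len(energies) / n_models
    selected = (de <= config.delta_e_threshold
                and valid_frac >= config.min_valid_fraction)
    return MutationResult(
        mutation_id=mid, chain_id=spec.chain_id, number=spec.number,
        wt_aa=AA3_TO_1[wt3], mut_aa=AA3_TO_1[spec.target3],
        energies=energies, n_filtered=n_filtered,
        median=float(np.median(energies)), mean=float(np.mean(energies)),
        delta_e=de_med, delta_e_mean=de_mean, selected=selected,
        n_converged=ensemble.n_converged(), n_models=n_models)


def rank_and_select(results: list[MutationResult],
                    config: ScreeningConfig) -> list[MutationResult]:
    """Sort ascending by delta-E (most favorable first).

    No-contact mutations are excluded from the ranking and appended at the
    end.  Ties break deterministically by (chain, position, target AA).
    """
    if not results:
        raise ValueError("no results to rank")
    ranked = [r for r in results if not r.excluded]
    excluded = [r for r in results if r.excluded]
    ranked.sort(key=lambda r: (r.delta_e, r.chain_id, r.number, r.mut_aa))
    excluded.sort(key=lambda r: (r.chain_id, r.number, r.mut_aa))
    return ranked + excluded


def run_screen(
    structure: ComplexStructure,
    selection: CdrSelection,
    config: ScreeningConfig,
    library: RotamerLibrary | None = None,
    params: ForceFieldParams | None = None,
) -> tuple[list[MutationResult], EnergyHistogram, float]:
    """Full screen: WT reference, per-mutation ensembles, ranking."""
    hist, wt_stat, _ = wt_reference(structure, config, library, params)
    wt_median, wt_mean = hist.median, hist.mean
    specs = enumerate_library(structure, selection)
    results = [
        screen_mutation(structure, spec, wt_median, wt_mean, config,
                        library, params)
        for spec in specs
    ]
    return rank_and_select(results, config), hist, wt_stat
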
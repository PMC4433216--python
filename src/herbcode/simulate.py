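"""Synthetic reference libraries, market queries and chemistry assays.

The generator reproduces the statistical structure the authentication
pipeline assumes, so the whole workflow runs and can be validated with no
downloads:

* a multi-genus reference library (several vouchers per species) whose
  sequences evolve along fixed star-shaped genus trees under a two-rate
  (Kimura-type) substitution process with transition/transversion ratio
  kappa — branch lengths are set so expected pairwise divergences match the
  intraspecific, congeneric and intergeneric scales, and the K2P distance
  estimator is consistent for them;
* market query samples that are authentic, congeneric substitutes or
  intergeneric substitutes (the latter drawn from off-target genera present
  in the library but never sold), with per-marker amplification dropout and
  occasional truncation below 200 bp;
* chemistry assays in which authentic samples carry the marker around 1.5x
  the pharmacopoeial minimum (lognormal noise) and substitutes cross-react
  with a small probability.

All randomness derives from one root seed through fixed per-stage
sub-streams, so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import ChemicalSpec
from .seqstore import MarkerSequence, decode_bases

DEFAULT_MARKER_LENGTHS = {"matK": 500, "rbcL": 550, "ITS2": 350}

# sub-stream labels (SeedSequence spawn keys): one per generation stage
_STAGE_LIBRARY, _STAGE_QUERIES, _STAGE_CHEMISTRY = 0, 1, 2

CATEGORIES = ("authentic", "congeneric_substitute", "intergeneric_substitute")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic market survey."""

    n_genera: int = 8
    species_per_genus: int = 3
    refs_per_species: int = 5
    n_offtarget_genera: int = 3
    seq_length_per_marker: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_LENGTHS)
    )
    kappa: float = 2.0
    intra_scale: float = 0.002
    inter_scale: float = 0.03
    intergenus_scale: float = 0.10
    n_queries: int = 200
    p_authentic: float = 0.3
    p_congeneric_sub: float = 0.1
    p_intergeneric_sub: float = 0.6
    p_marker_dropout: float = 0.15
    p_short_fragment: float = 0.1
    chem_cross_react: float = 0.1
    conc_lognorm_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_authentic, self.p_congeneric_sub, self.p_intergeneric_sub,
                 self.p_marker_dropout, self.p_short_fragment, self.chem_cross_react)
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        total = self.p_authentic + self.p_congeneric_sub + self.p_intergeneric_sub
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"category probabilities sum to {total}, not 1")
        for name in ("n_genera", "species_per_genus", "refs_per_species", "n_queries"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_offtarget_genera < 0:
            raise ConfigurationError("n_offtarget_genera must be >= 0")
        if not (0.0 <= self.intra_scale < self.inter_scale < self.intergenus_scale):
            raise ConfigurationError("need intra_scale < inter_scale < intergenus_scale")
        if self.p_congeneric_sub > 0 and self.species_per_genus < 2:
            raise ConfigurationError("congeneric substitutes need >= 2 species per genus")
        if self.p_intergeneric_sub > 0 and self.n_offtarget_genera < 1:
            raise ConfigurationError("intergeneric substitutes need an off-target genus")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))

    def to_json(self) -> str:
        d = asdict(self)
        d["seq_length_per_marker"] = dict(d["seq_length_per_marker"])
        return json.dumps(d, indent=2, sort_keys=True)


def _k2p_step_probs(t: float, kappa: float) -> tuple[float, float, float]:
    """(stay, transition, each-transversion) probabilities after time t.

    Rates are normalized so t is in expected substitutions per site
    (alpha + 2 beta = 1 with alpha/beta = kappa); then the K2P distance
    estimator recovers t in expectation.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e_tv = np.exp(-4.0 * beta * t)
    e_ts = np.exp(-2.0 * (alpha + beta) * t)
    p_tv_each = 0.25 * (1.0 - e_tv)
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_stay = 1.0 - p_ts - 2.0 * p_tv_each
    return p_stay, p_ts, p_tv_each


def evolve(codes: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a coded sequence for branch length t under the two-rate process."""
    if t == 0.0:
        return codes.copy()
    p_stay, p_ts, p_tv = _k2p_step_probs(t, kappa)
    u = rng.random(codes.shape)
    ts_partner = codes ^ 1  # A<->G, C<->T
    tv1 = np.where(codes < 2, np.uint8(2), np.uint8(0))  # other base class
    tv2 = tv1 + 1
    out = codes.copy()
    out = np.where(u < p_stay, out, np.where(
        u < p_stay + p_ts, ts_partner, np.where(u < p_stay + p_ts + p_tv, tv1, tv2)
    ))
    return out.astype(np.uint8)


@dataclass
class ReferenceSimulation:
    config: SimulationConfig
    taxonomy: dict[str, tuple[str, str]]  # species -> (genus, family)
    target_species: list[str]  # the marketed species, one per target genus
    sequences: dict[str, list[MarkerSequence]]  # marker -> reference records
    ancestors: dict[str, dict[str, np.ndarray]]  # marker -> species -> coded ancestor
    genus_trees: dict[str, str]  # genus -> newick of the species radiation

    @property
    def species(self) -> list[str]:
        return sorted(self.taxonomy)

    def species_of_genus(self, genus: str) -> list[str]:
        return sorted(s for s, (g, _) in self.taxonomy.items() if g == genus)


def _genus_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    targets = [f"Genus{str(i + 1).zfill(2)}" for i in range(config.n_genera)]
    offtargets = [f"Offgenus{str(i + 1).zfill(2)}" for i in range(config.n_offtarget_genera)]
    return targets, offtargets


def simulate_reference_library(config: SimulationConfig) -> ReferenceSimulation:
    """Generate the per-marker reference library and its taxonomy.

    Topology: one global root; genus ancestors branch from it at depth
    intergenus_scale/2; species ancestors radiate from each genus ancestor at
    depth inter_scale/2; vouchers hang off species ancestors at depth
    intra_scale/2.  Expected pairwise divergence is therefore ~intra_scale
    within species, ~inter_scale (+intra) within a genus and
    ~intergenus_scale between genera.
    """
    rng = config.rng(_STAGE_LIBRARY)
    targets, offtargets = _genus_names(config)
    genera = targets + offtargets
    taxonomy: dict[str, tuple[str, str]] = {}
    for gi, genus in enumerate(genera):
        family = f"Family{str(gi // 2 + 1).zfill(2)}"
        for si in range(config.species_per_genus):
            taxonomy[f"{genus} species{si + 1}"] = (genus, family)
    target_species = [f"{g} species1" for g in targets]

    sequences: dict[str, list[MarkerSequence]] = {}
    ancestors: dict[str, dict[str, np.ndarray]] = {}
    for marker, length in config.seq_length_per_marker.items():
        root = rng.integers(0, 4, size=length).astype(np.uint8)
        marker_refs: list[MarkerSequence] = []
        marker_anc: dict[str, np.ndarray] = {}
        for genus in genera:
            genus_root = evolve(root, config.intergenus_scale / 2.0, config.kappa, rng)
            for species in [f"{genus} species{i + 1}" for i in range(config.species_per_genus)]:
                anc = evolve(genus_root, config.inter_scale / 2.0, config.kappa, rng)
                marker_anc[species] = anc
                for vi in range(config.refs_per_species):
                    seq = evolve(anc, config.intra_scale / 2.0, config.kappa, rng)
                    marker_refs.append(
                        MarkerSequence(
                            sample_id=f"{species.replace(' ', '_')}_v{vi + 1}",
                            marker=marker,
                            bases=decode_bases(seq),
                            role="reference",
                            species_label=species,
                        )
                    )
        sequences[marker] = marker_refs
        ancestors[marker] = marker_anc

    half = config.inter_scale / 2.0
    genus_trees = {
        genus: "(" + ",".join(
            f"{genus}_species{i + 1}:{half:.6f}" for i in range(config.species_per_genus)
        ) + ");"
        for genus in genera
    }
    return ReferenceSimulation(config, taxonomy, target_species, sequences, ancestors, genus_trees)


@dataclass
class QuerySimulation:
    sequences: dict[str, list[MarkerSequence]]  # marker -> query records
    truth: pd.DataFrame  # one row per query sample


def simulate_queries(config: SimulationConfig, library: ReferenceSimulation) -> QuerySimulation:
    """Draw market samples and their truth table from the reference library."""
    if set(config.seq_length_per_marker) != set(library.sequences):
        raise ValueError("config markers do not match the library's markers")
    rng = config.rng(_STAGE_QUERIES)
    targets, offtargets = _genus_names(config)
    markers = list(config.seq_length_per_marker)
    probs = [config.p_authentic, config.p_congeneric_sub, config.p_intergeneric_sub]
    rows = []
    seqs: dict[str, list[MarkerSequence]] = {m: [] for m in markers}
    for qi in range(config.n_queries):
        sample_id = f"Q{str(qi + 1).zfill(4)}"
        labelled = library.target_species[rng.integers(0, len(library.target_species))]
        genus = library.taxonomy[labelled][0]
        category = CATEGORIES[rng.choice(3, p=probs)]
        if category == "authentic":
            true_species = labelled
        elif category == "congeneric_substitute":
            others = [s for s in library.species_of_genus(genus) if s != labelled]
            true_species = others[rng.integers(0, len(others))]
        else:
            off_genus = offtargets[rng.integers(0, len(offtargets))]
            candidates = library.species_of_genus(off_genus)
            true_species = candidates[rng.integers(0, len(candidates))]
        markers_present = []
        for marker in markers:
            dropped = rng.random() < config.p_marker_dropout
            short = rng.random() < config.p_short_fragment
            cut = int(rng.integers(100, 200))
            if dropped:
                continue
            seq = evolve(
                library.ancestors[marker][true_species],
                config.intra_scale / 2.0,
                config.kappa,
                rng,
            )
            if short:
                seq = seq[:cut]
            markers_present.append(marker)
            seqs[marker].append(
                MarkerSequence(
                    sample_id=sample_id,
                    marker=marker,
                    bases=decode_bases(seq),
                    role="query",
                )
            )
        rows.append(
            {
                "sample_id": sample_id,
                "true_species": true_species,
                "labelled_species": labelled,
                "category": category,
                "markers": ";".join(markers_present),
            }
        )
    truth = pd.DataFrame(rows)
    assert truth.sample_id.is_unique
    return QuerySimulation(seqs, truth)


def default_chem_specs(library: ReferenceSimulation) -> dict[str, ChemicalSpec]:
    """One pharmacopoeial specification per marketed species (1.0 unit minimum)."""
    return {
        sp: ChemicalSpec(sp, f"{sp} marker", 1.0, "percent", "HPLC")
        for sp in library.target_species
    }


def simulate_chemistry(
    truth: pd.DataFrame,
    specs: Mapping[str, ChemicalSpec],
    config: SimulationConfig,
    detection_floor_frac: float = 0.3,
) -> pd.DataFrame:
    """Assay table for the truth table's samples.

    Authentic samples carry the marker with concentration lognormal around
    1.5x the species minimum; substitutes cross-react with probability
    ``chem_cross_react`` (around 1.0x the minimum), otherwise the marker is
    absent and the measured value is zero or a sub-minimum trace.  The TLC
    flag reads present when the concentration exceeds the detection floor
    (``detection_floor_frac`` of the minimum).
    """
    missing = set(truth.labelled_species) - set(specs)
    if missing:
        raise KeyError(f"no chemical specification for {sorted(missing)}")
    rng = config.rng(_STAGE_CHEMISTRY)
    rows = []
    for row in truth.itertuples():
        spec = specs[row.labelled_species]
        authentic = row.category == "authentic"
        if authentic:
            marker_present = True
            conc = 1.5 * spec.min_concentration * float(
                np.exp(config.conc_lognorm_sigma * rng.standard_normal())
            )
        elif rng.random() < config.chem_cross_react:
            marker_present = True
            conc = 1.0 * spec.min_concentration * float(
                np.exp(config.conc_lognorm_sigma * rng.standard_normal())
            )
        else:
            marker_present = False
            conc = 0.0 if rng.random() < 0.5 else float(
                rng.uniform(0.0, detection_floor_frac * spec.min_concentration)
            )
        tlc = "present" if conc > detection_floor_frac * spec.min_concentration else "absent"
        rows.append(
            {
                "sample_id": row.sample_id,
                "chem_marker_present": marker_present,
                "tlc": tlc,
                "concentration": conc,
                "unit": spec.unit,
            }
        )
    return pd.DataFrame(rows)
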
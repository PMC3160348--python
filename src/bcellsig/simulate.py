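"""Synthetic expression studies with planted structure.

The generator emulates the shape of a case/control B-cell microarray
study: a large probe panel in which only a minority of genes are
expressed, a small cohort (9 controls vs 17 patients by default), and a
planted patient subgroup that carries a correlated module of several
hundred up/down shifted genes.  A companion generator produces a
ligand-stimulation compendium (mouse symbols with log2 fold changes)
in which one target ligand's signature overlaps the planted module
with a prescribed size and directional concordance, while decoy
ligands overlap only by chance.

Every draw is governed by ``SimulationConfig.seed``; runs are
bit-reproducible.  Ground truth (subgroup members, module directions,
target ligand) is returned alongside the data so downstream stages can
be tested by parameter recovery.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import (
    CONTROL,
    PATIENT,
    ConfigurationError,
    ExpressionMatrix,
    SampleAnnotation,
)
from .signature import DirectionalGeneList, HomologMap, LigandCompendium

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_study",
    "simulate_ligand_compendium",
    "tiny_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic study.

    The defaults reproduce the study shape the pipeline targets: 9
    controls vs 17 patients, a 5-patient subgroup carrying an 800-gene
    module shifted by +/-1 log2 unit, roughly a third of genes
    expressed above the log2 threshold of 4, and a 33-ligand
    compendium whose target ligand shares 112 genes with the module,
    101 of them changing in the same direction.
    """

    n_genes: int = 20_000
    n_controls: int = 9
    n_patients: int = 17
    subgroup_size: int = 5
    module_size: int = 800
    effect_size_log2: float = 1.0
    frac_module_up: float = 0.5
    noise_sd: float = 0.4
    expressed_fraction_target: float = 0.33
    n_ligands: int = 33
    signature_overlap: int = 112
    signature_concordance: float = 101 / 112
    seed: int = 0
    # baseline mixture (log2 scale): unexpressed and expressed components
    unexpressed_mean: float = 2.5
    unexpressed_sd: float = 0.5
    expressed_mean: float = 7.0
    expressed_sd: float = 1.5
    expression_threshold: float = 4.0
    # optional per-array additive shift (log2) to exercise quantile normalization
    array_effect_sd: float = 0.0
    # non-module genes added to the target ligand signature
    target_signature_extra: int = 200

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_controls < 1 or self.n_patients < 1:
            raise ConfigurationError("counts must be positive")
        if self.subgroup_size > self.n_patients:
            raise ConfigurationError("subgroup_size exceeds n_patients")
        if self.module_size > self.n_genes:
            raise ConfigurationError("module_size exceeds n_genes")
        if self.signature_overlap > self.module_size:
            raise ConfigurationError("signature_overlap exceeds module_size")
        if not 0.0 <= self.signature_concordance <= 1.0:
            raise ConfigurationError("signature_concordance must lie in [0, 1]")
        if not 0.0 <= self.frac_module_up <= 1.0:
            raise ConfigurationError("frac_module_up must lie in [0, 1]")
        if self.noise_sd < 0 or self.effect_size_log2 < 0:
            raise ConfigurationError("noise_sd and effect_size_log2 must be >= 0")

    def expressed_weight(self) -> float:
        """Mixture weight of the expressed component.

        Chosen so that the expected fraction of genes whose baseline
        mean clears the expression threshold equals
        ``expressed_fraction_target`` (closed form from the two normal
        component tail probabilities).
        """
        p_unexpr = norm.sf(
            (self.expression_threshold - self.unexpressed_mean) / self.unexpressed_sd
        )
        p_expr = norm.sf(
            (self.expression_threshold - self.expressed_mean) / self.expressed_sd
        )
        w = (self.expressed_fraction_target - p_unexpr) / (p_expr - p_unexpr)
        return float(np.clip(w, 0.0, 1.0))


@dataclass
class GroundTruth:
    """What was planted: subgroup members, module directions, target ligand."""

    subgroup_sample_ids: list[str]
    module_directions: dict[str, int]  # gene symbol -> +1 (up in subgroup) / -1
    target_ligand: str | None = None
    planted_concordant_count: int | None = None

    @property
    def module_gene_ids(self) -> list[str]:
        return list(self.module_directions)

    def module_list(self) -> DirectionalGeneList:
        """The planted module as a directional gene list."""
        return DirectionalGeneList.from_dict(self.module_directions)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["module_directions"] = {k: int(v) for k, v in d["module_directions"].items()}
        return cls(**d)


def _symbols(n: int) -> np.ndarray:
    return np.array([f"GENE{i + 1:05d}" for i in range(n)])


def simulate_study(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, GroundTruth]:
    """Draw one synthetic study.

    Per-gene baseline means come from a two-component log2 mixture
    ("unexpressed" around 2.5, "expressed" around 7) whose weights are
    calibrated so the expressed fraction matches the target.  All
    samples share the gene baselines; i.i.d. gaussian noise with
    ``noise_sd`` is added on the log2 scale.  Module genes are chosen
    among well-expressed genes and shifted by ``+/-effect_size_log2``
    in the subgroup samples only, with per-gene direction drawn
    Bernoulli(``frac_module_up``).  Controls and non-subgroup patients
    are exchangeable by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    n_samples = config.n_controls + config.n_patients

    w = config.expressed_weight()
    is_expressed = rng.random(n_genes) < w
    baseline = np.where(
        is_expressed,
        rng.normal(config.expressed_mean, config.expressed_sd, n_genes),
        rng.normal(config.unexpressed_mean, config.unexpressed_sd, n_genes),
    )

    # Module genes must stay clearly expressed even when shifted down,
    # so draw them from genes with comfortable headroom above threshold.
    margin = config.expression_threshold + config.effect_size_log2 + 0.5
    eligible = np.flatnonzero(is_expressed & (baseline >= margin))
    if eligible.size < config.module_size:
        raise ConfigurationError(
            f"only {eligible.size} genes eligible for a module of {config.module_size}"
        )
    module_idx = np.sort(rng.choice(eligible, size=config.module_size, replace=False))
    directions = np.where(rng.random(config.module_size) < config.frac_module_up, 1, -1)

    control_ids = [f"C{i + 1:02d}" for i in range(config.n_controls)]
    patient_ids = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    sample_ids = control_ids + patient_ids
    subgroup = sorted(
        rng.choice(patient_ids, size=config.subgroup_size, replace=False).tolist()
    )

    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, (n_genes, n_samples))
    col_of = {s: j for j, s in enumerate(sample_ids)}
    sub_cols = [col_of[s] for s in subgroup]
    values[np.ix_(module_idx, sub_cols)] += (
        config.effect_size_log2 * directions[:, None]
    )
    if config.array_effect_sd > 0:
        values += rng.normal(0.0, config.array_effect_sd, (1, n_samples))

    symbols = _symbols(n_genes)
    probe_ids = [f"PS{i + 1:06d}_at" for i in range(n_genes)]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        pd.Series(symbols, index=probe_ids),
    )
    annotation = SampleAnnotation.from_groups(
        {s: (CONTROL if s in control_ids else PATIENT) for s in sample_ids}
    )
    truth = GroundTruth(
        subgroup_sample_ids=subgroup,
        module_directions={
            symbols[g]: int(d) for g, d in zip(module_idx, directions)
        },
    )
    return matrix, annotation, truth


def _mouse_case(symbol: str) -> str:
    """Mouse-style symbol casing (``GENE00012`` -> ``Gene00012``)."""
    return symbol.capitalize()


def simulate_ligand_compendium(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[LigandCompendium, HomologMap, GroundTruth]:
    """Draw a ligand-response compendium tied to a simulated study.

    The target ligand's signature shares exactly
    ``config.signature_overlap`` genes with the planted module;
    ``round(overlap * concordance)`` of them carry the module's
    planted direction and the rest the opposite sign.  Additional
    non-module genes pad the target signature; decoy ligands draw
    their signatures uniformly from the gene panel with random signs,
    so they overlap the module only by chance.  All fold changes are
    reported at the 4 h timepoint on mouse-cased symbols; the homolog
    map covers the entire panel by the same-symbol-name rule.
    """
    config.validate()
    if config.signature_overlap > len(truth.module_directions):
        raise ConfigurationError("signature_overlap exceeds planted module size")
    # independent stream so the compendium can be redrawn without
    # disturbing the study; still fully determined by config.seed
    rng = np.random.default_rng([config.seed, 7])

    all_symbols = _symbols(config.n_genes)
    module_symbols = np.array(truth.module_gene_ids)
    module_dir = truth.module_directions
    non_module = np.setdiff1d(all_symbols, module_symbols)

    ligand_names = [f"ligand_{i + 1:02d}" for i in range(config.n_ligands)]
    target = ligand_names[int(rng.integers(config.n_ligands))]
    n_conc = int(round(config.signature_overlap * config.signature_concordance))

    rows: list[tuple[str, str, float, float]] = []

    # target ligand: planted overlap with the module
    overlap_genes = rng.choice(
        module_symbols, size=config.signature_overlap, replace=False
    )
    conc_flags = np.zeros(config.signature_overlap, dtype=bool)
    conc_flags[:n_conc] = True
    rng.shuffle(conc_flags)
    for sym, conc in zip(overlap_genes, conc_flags):
        sign = module_dir[sym] if conc else -module_dir[sym]
        mag = rng.uniform(0.7, 2.5)  # comfortably above log2(1.5)
        rows.append((target, _mouse_case(sym), sign * mag, 4.0))
    extra = rng.choice(
        non_module,
        size=min(config.target_signature_extra, non_module.size),
        replace=False,
    )
    for sym in extra:
        sign = 1 if rng.random() < 0.5 else -1
        rows.append((target, _mouse_case(sym), sign * rng.uniform(0.7, 2.5), 4.0))

    # decoy ligands: uniform draws from the whole panel, random signs
    for name in ligand_names:
        if name == target:
            continue
        size = int(rng.integers(80, 400))
        genes = rng.choice(all_symbols, size=size, replace=False)
        signs = np.where(rng.random(size) < 0.5, 1.0, -1.0)
        mags = rng.uniform(0.7, 2.5, size)
        for sym, fc in zip(genes, signs * mags):
            rows.append((name, _mouse_case(sym), float(fc), 4.0))

    compendium = LigandCompendium(
        pd.DataFrame(rows, columns=["ligand", "symbol", "log2fc", "timepoint_h"])
    )
    homolog = HomologMap.same_symbol([_mouse_case(s) for s in all_symbols])
    truth_out = replace_truth(truth, target, n_conc)
    return compendium, homolog, truth_out


def replace_truth(truth: GroundTruth, target: str, n_conc: int) -> GroundTruth:
    return GroundTruth(
        subgroup_sample_ids=list(truth.subgroup_sample_ids),
        module_directions=dict(truth.module_directions),
        target_ligand=target,
        planted_concordant_count=n_conc,
    )


def tiny_fixture() -> tuple[ExpressionMatrix, SampleAnnotation]:
    """A deterministic 12-gene, 6-sample dataset with hand-checkable values.

    Contains genes that sit entirely below the expression threshold of
    4 (removed by filtering), a gene whose two group means are exactly
    equal (SAM d = 0), and an immunoglobulin-symbol probe.  Sample
    profiles are interleaved across groups so no patient-only cluster
    stands out.
    """
    samples = ["C1", "C2", "C3", "P1", "P2", "P3"]
    data = {
        # probe: (symbol, values C1 C2 C3 P1 P2 P3)
        "TP001_at": ("ACTB", [9.0, 9.1, 8.9, 9.0, 9.1, 8.9]),
        "TP002_at": ("GAPDH", [8.0, 8.2, 8.1, 8.1, 8.0, 8.2]),
        "TP003_at": ("XBP1", [6.0, 6.5, 6.2, 7.5, 7.8, 7.6]),
        "TP004_at": ("EGR1", [7.4, 7.2, 7.3, 6.1, 6.0, 6.2]),
        "TP005_at": ("CD1C", [5.0, 5.2, 5.1, 4.6, 4.4, 4.5]),
        "TP006_at": ("EQMEAN", [6.0, 7.0, 8.0, 8.0, 7.0, 6.0]),  # equal group means
        "TP007_at": ("LOW1", [2.0, 2.5, 3.0, 2.2, 2.8, 3.1]),  # below threshold
        "TP008_at": ("LOW2", [3.9, 3.9, 3.9, 3.9, 3.9, 3.9]),  # below threshold
        "TP009_at": ("LOW3", [1.0, 1.5, 1.2, 1.1, 1.4, 1.3]),  # below threshold
        "TP010_at": ("IGHG1", [7.0, 6.8, 7.1, 8.5, 8.6, 8.4]),
        # pairing genes dominate distances and tie each patient to a
        # control, so no patient-only cluster exists
        "TP011_at": ("MIX1", [10.0, 5.0, 5.0, 10.0, 5.0, 5.0]),
        "TP012_at": ("", [5.0, 10.0, 5.0, 5.0, 10.0, 5.0]),  # unannotated probe
    }
    values = pd.DataFrame(
        {p: vals for p, (_, vals) in data.items()}, index=samples
    ).T
    symbols = pd.Series({p: sym for p, (sym, _) in data.items()})
    matrix = ExpressionMatrix(values, symbols)
    annotation = SampleAnnotation.from_groups(
        {s: (CONTROL if s.startswith("C") else PATIENT) for s in samples}
    )
    return matrix, annotation
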
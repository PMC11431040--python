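"""End-to-end pipeline: simulate -> profile -> hotspots -> structure -> CE.

The library core behind the command-line driver. A :class:`RunConfig`
(YAML-serializable) fully determines a run; re-running with the same config
and seed reproduces every numeric output byte for byte, and every output
file embeds the config hash and seed for provenance.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ce as ce_mod
from . import synthetic_reference as ref
from .construct import (
    MrnaConstruct,
    load_construct,
    read_primer_table,
)
from .degmodel import (
    DegradationBaseline,
    classify_high_intensity,
    composition_stats,
    find_hotspots,
    fold_change,
    write_hotspots_json,
)
from .reactivity import (
    ReactivityProfile,
    assemble_sections,
    mean_reactivity,
    normalize_profile,
    peaks_to_positions,
    subtract_control,
)
from .simulate import (
    CleavageModel,
    StressDose,
    cleavage_propensity,
    simulate_electropherogram,
    simulate_fragments,
    simulate_rt_traces,
)
from .structure import SecondaryStructure, annotate_hotspot_structure, read_dotbracket

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RegimeConfig", "run_pipeline", "PipelineResult"]

DOSE_UNITS = {"freeze_thaw": "cycles", "heat_37C": "hours"}


@dataclass
class RegimeConfig:
    """One stress regime: its dose ladder and baseline parameters."""

    doses: list[float] = field(default_factory=list)
    per_event_rate: float | None = None  # cuts/molecule/unit; None = default
    baseline_A: float | None = None  # None = derive from the dose gradient
    baseline_q: float = 0.0
    planted_hotspots: list[tuple[int, int, float]] = field(default_factory=list)


@dataclass
class RunConfig:
    """Fully serialized run description (see docs/methods.md for units)."""

    seed: int = 0
    out_dir: str = "mprtseq_out"
    construct: str | dict = "reference"  # "reference" or paths dict
    structure: str | None = "reference"  # "reference", a dot-bracket path, or None
    regimes: dict[str, RegimeConfig] = field(
        default_factory=lambda: {
            "freeze_thaw": RegimeConfig(doses=[5, 10, 20]),
            "heat_37C": RegimeConfig(doses=[24, 48]),
        }
    )
    profiles_source: str = "simulate"  # "simulate" or "reference" (bundled fixture)
    n_molecules: int = 10_000
    noise_sd: float = 0.0
    sizing_sd: float = 25.0
    normalize: str = "none"  # {"anchored", "per_section", "none"}
    hotspot_min_high: int = 2
    hotspot_max_gap: int = 3
    require_all_conditions: bool = True
    ce_window: tuple[float, float] = ce_mod.DEFAULT_MAIN_PEAK_WINDOW
    exclusion_margin: int = 0

    def __post_init__(self) -> None:
        if self.normalize not in {"anchored", "per_section", "none"}:
            raise ValueError(f"unknown normalize mode {self.normalize!r}")
        if self.profiles_source not in {"simulate", "reference"}:
            raise ValueError(f"unknown profiles_source {self.profiles_source!r}")
        if not self.regimes:
            raise ValueError("at least one stress regime is required")
        for name, rc in list(self.regimes.items()):
            if isinstance(rc, dict):
                self.regimes[name] = RegimeConfig(**rc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    construct: MrnaConstruct
    profiles: dict[str, dict[float, ReactivityProfile]]  # regime -> dose -> profile
    regime_profiles: dict[str, ReactivityProfile]  # gradient-average per regime
    baselines: dict[str, DegradationBaseline]
    hotspots: list
    integrity: dict[str, dict[float, ce_mod.IntegrityResult]]
    composition: dict[str, dict]
    out_dir: Path


def _load_inputs(config: RunConfig) -> tuple[MrnaConstruct, SecondaryStructure | None]:
    if config.construct == "reference":
        construct = ref.reference_construct()
    else:
        paths = dict(config.construct)
        primers = read_primer_table(paths["primers"]) if "primers" in paths else []
        construct = load_construct(paths["fasta"], paths["annotation"], primers)
    if config.structure == "reference":
        structure = ref.reference_structure()
    elif config.structure:
        _, structure = read_dotbracket(config.structure)
    else:
        structure = None
    return construct, structure


def _profile_from_fragments(
    fragments, construct: MrnaConstruct, config: RunConfig, treatment: str, rng
) -> ReactivityProfile:
    tables = simulate_rt_traces(fragments, construct.primers, config.noise_sd, rng)
    maps = {
        t.primer: peaks_to_positions(t, p)
        for t, p in zip(tables, construct.primers)
    }
    return assemble_sections(
        maps,
        construct.section_map(),
        len(construct),
        primers=construct.primers,
        treatment=treatment,
        exclusion_margin=config.exclusion_margin,
    )


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full workflow and write the report bundle.

    Stages: simulate stressed fragment populations per regime and dose ->
    RT-stop read-out and section assembly -> control referencing ->
    baseline classification and cross-regime hotspot calling -> secondary
    structure annotation -> CE integrity -> TSV/BED/JSON outputs, figures
    and a Markdown report.
    """
    construct, structure = _load_inputs(config)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"# mprtseq config={config.digest()} seed={config.seed}\n"
    master = np.random.default_rng(config.seed)

    profiles: dict[str, dict[float, ReactivityProfile]] = {}
    integrity: dict[str, dict[float, ce_mod.IntegrityResult]] = {}
    regime_profiles: dict[str, ReactivityProfile] = {}
    baselines: dict[str, DegradationBaseline] = {}

    if config.profiles_source == "reference":
        # bundled deterministic fixture: profiles are already assembled,
        # normalized and control-subtracted; no simulation or CE stage
        for regime, prof in ref.reference_profiles().items():
            if regime not in config.regimes:
                continue
            rc = config.regimes[regime]
            profiles[regime] = {}
            integrity[regime] = {}
            regime_profiles[regime] = prof
            default = ref.reference_bundle().baselines[regime]
            baselines[regime] = DegradationBaseline(
                A=rc.baseline_A if rc.baseline_A is not None else default.A,
                q=rc.baseline_q if rc.baseline_A is not None else default.q,
                regime=regime,
            )
        if not regime_profiles:
            raise ValueError("no configured regime matches the reference fixture")
        return _finish(
            config, construct, structure, out, tag, profiles, regime_profiles,
            baselines, integrity,
        )

    for regime, rc in config.regimes.items():
        model = CleavageModel.for_regime(regime, planted_hotspots=list(rc.planted_hotspots))
        if rc.per_event_rate is not None:
            model.per_event_rate = rc.per_event_rate
        propensity = cleavage_propensity(construct, structure, model)
        rng = np.random.default_rng(master.integers(2**31))

        control_frags = simulate_fragments(
            propensity, StressDose(regime, 0.0), config.n_molecules, rng,
            model.per_event_rate,
        )
        control = _profile_from_fragments(control_frags, construct, config, "control", rng)
        control_factors = None
        if config.normalize != "none":
            control = normalize_profile(control, per_section=True)
            control_factors = control.normalization

        profiles[regime] = {}
        integrity[regime] = {}
        for dose in rc.doses:
            frags = simulate_fragments(
                propensity, StressDose(regime, float(dose)), config.n_molecules,
                rng, model.per_event_rate,
            )
            prof = _profile_from_fragments(
                frags, construct, config, f"{regime}:{dose}", rng
            )
            if config.normalize == "per_section":
                prof = normalize_profile(prof, per_section=True)
            elif config.normalize == "anchored":
                prof = normalize_profile(prof, per_section=True, factors=control_factors)
            prof = subtract_control(prof, control)
            profiles[regime][float(dose)] = prof

            eph = simulate_electropherogram(
                frags, config.sizing_sd, f"{regime}_{dose}"
            )
            integrity[regime][float(dose)] = ce_mod.integrity_percent(
                eph, *config.ce_window
            )
            ce_mod.write_trace_csv(eph, out / f"electropherogram_{regime}_{dose}.csv")

        if not profiles[regime]:
            raise ValueError(f"regime {regime!r} has an empty dose ladder")
        # gradient average across the dose ladder (the regime's overall
        # degradation picture, and the source of its baseline A)
        stack = np.vstack([p.values for p in profiles[regime].values()])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            avg_values = np.nanmean(stack, axis=0)
        regime_prof = next(iter(profiles[regime].values())).copy_with(
            avg_values, treatment=f"{regime}:gradient_mean"
        )
        regime_profiles[regime] = regime_prof
        A = rc.baseline_A if rc.baseline_A is not None else mean_reactivity(regime_prof)
        if A <= 0:
            # a null (zero-dose) run has no degradation signal at all; any
            # positive baseline then classifies every position low
            logger.info("regime %s: zero mean reactivity, using unit baseline", regime)
            A = 1.0
        baselines[regime] = DegradationBaseline(A=A, q=rc.baseline_q, regime=regime)

    return _finish(
        config, construct, structure, out, tag, profiles, regime_profiles,
        baselines, integrity,
    )


def _finish(
    config: RunConfig, construct, structure, out: Path, tag: str,
    profiles, regime_profiles, baselines, integrity,
) -> "PipelineResult":
    """Shared tail: hotspot calling, structure annotation, outputs."""
    masks = {
        regime: classify_high_intensity(regime_profiles[regime], baselines[regime])
        for regime in regime_profiles
    }
    hotspots = find_hotspots(
        masks,
        min_high=config.hotspot_min_high,
        max_gap=config.hotspot_max_gap,
        require_all_conditions=config.require_all_conditions,
        sequence=construct.sequence,
    )
    composition = {
        regime: composition_stats(mask, construct.sequence)
        for regime, mask in masks.items()
    }
    for h in hotspots:
        for regime in regime_profiles:
            h.fold_changes[regime] = fold_change(
                regime_profiles[regime], h.start, h.end, baselines[regime].A
            )
        if structure is not None and h.end <= len(structure):
            h.motif = annotate_hotspot_structure(h, structure)

    _write_outputs(
        out, tag, config, construct, profiles, regime_profiles, baselines,
        hotspots, integrity, composition,
    )
    return PipelineResult(
        config=config,
        construct=construct,
        profiles=profiles,
        regime_profiles=regime_profiles,
        baselines=baselines,
        hotspots=hotspots,
        integrity=integrity,
        composition=composition,
        out_dir=out,
    )


def _write_outputs(
    out: Path, tag: str, config: RunConfig, construct, profiles,
    regime_profiles, baselines, hotspots, integrity, composition,
) -> None:
    for regime, prof in regime_profiles.items():
        path = out / f"profile_{regime}.tsv"
        with open(path, "w") as fh:
            fh.write(tag)
            prof.to_frame(construct).to_csv(fh, sep="\t", index=False, float_format="%.6g")
    with open(out / "hotspots.bed", "w") as fh:
        fh.write(tag)
        for i, h in enumerate(hotspots, 1):
            fh.write(f"mrna\t{h.start}\t{h.end}\thotspot_{i}\t{h.sequence}\t+\n")
    write_hotspots_json(hotspots, out / "hotspots.json")
    payload = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "baselines": {
            r: {"A": b.A, "q": b.q} for r, b in baselines.items()
        },
        "hotspots": [h.to_dict() for h in hotspots],
        "composition": composition,
        "integrity": {
            r: {str(d): res.to_dict() for d, res in by_dose.items()}
            for r, by_dose in integrity.items()
        },
        "mean_reactivity": {
            r: {str(d): mean_reactivity(p) for d, p in by_dose.items()}
            for r, by_dose in profiles.items()
        },
    }
    (out / "results.json").write_text(json.dumps(payload, indent=2) + "\n")
    _write_report(out, tag, payload, hotspots)
    _plot_profiles(out, regime_profiles, baselines)


def _write_report(out: Path, tag: str, payload: dict, hotspots) -> None:
    provenance = tag.strip("# \n")
    lines = [
        "# mRNA degradation mapping report",
        "",
        f"`{provenance}`",
        "",
        "## Baselines (IA(N) = A (1+q)^N)",
        "",
    ]
    for regime, b in payload["baselines"].items():
        lines.append(f"- {regime}: A = {b['A']:.4g}, q = {b['q']:.4g}")
    lines += ["", "## Mean assembled reactivity by dose", ""]
    for regime, by_dose in payload["mean_reactivity"].items():
        unit = DOSE_UNITS.get(regime, "units")
        for dose, m in by_dose.items():
            lines.append(f"- {regime}, {dose} {unit}: {m:.4g}")
    lines += ["", "## CE integrity by dose", ""]
    for regime, by_dose in payload["integrity"].items():
        unit = DOSE_UNITS.get(regime, "units")
        for dose, res in by_dose.items():
            lines.append(
                f"- {regime}, {dose} {unit}: {res['integrity_percent']:.1f}% "
                f"(average size {res['average_size_nt']:.0f} nt)"
            )
    lines += ["", f"## Hotspot calls ({len(hotspots)})", ""]
    for i, h in enumerate(hotspots, 1):
        motif = ""
        if h.motif is not None:
            feats = [
                name
                for name, flag in [
                    ("5' stem side", h.motif.on_5prime_stem_side),
                    ("apical loop", h.motif.has_apical_loop),
                    ("mid-stem bulge", h.motif.has_mid_stem_bulge),
                ]
                if flag
            ]
            motif = f" [{', '.join(feats)}]" if feats else ""
        folds = ", ".join(f"{r}: {f:.1f}x" for r, f in h.fold_changes.items())
        lines.append(f"{i}. {h.start}-{h.end} `{h.sequence}` ({folds}){motif}")
    (out / "report.md").write_text("\n".join(lines) + "\n")


def _plot_profiles(out: Path, regime_profiles, baselines) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        len(regime_profiles), 1, figsize=(8, 2.6 * len(regime_profiles)),
        squeeze=False,
    )
    for ax, (regime, prof) in zip(axes.ravel(), regime_profiles.items()):
        x = np.arange(1, len(prof) + 1)
        ax.plot(x, prof.values, lw=0.5, color="tab:blue")
        b = baselines[regime]
        ax.plot(x, b.A * (1 + b.q) ** x, color="tab:red", lw=1, ls="--",
                label=f"IA(N), A={b.A:.3g}")
        ax.set_ylabel("reactivity (AU)")
        ax.set_title(regime)
        ax.legend(loc="upper left", fontsize=8)
    axes.ravel()[-1].set_xlabel("nucleotide position")
    fig.tight_layout()
    fig.savefig(out / "profiles.png", dpi=120)
    plt.close(fig)
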
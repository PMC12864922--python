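"""Simulation and pipeline configuration.

`SimConfig` holds the study conditions the synthetic data emulates:
pulse-chase timepoints 0/12 h, RBNS protein concentrations 500/50/5 nM,
8-nt UMIs, paired-end amplicon reads, and desk-scale sample sizes chosen
so a full run completes on one CPU in minutes. `PipelineConfig` bundles a
SimConfig with the per-stage analysis parameters and round-trips through
YAML unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Tuple

import yaml

#: cutadapt-style 5' constant sequences on the two amplicon mates
FWD_ADAPTER = "GGCGGAAAGATCGCCGTGTAAGTTTGCTTCGATATCCGCATGCTA"
REV_ADAPTER = "CTGATCAGCGGGTTTCACTAGTGCGACCGCAAGAG"


@dataclass
class SimConfig:
    seed: int = 0
    # --- UTR set -----------------------------------------------------------
    n_target_utrs: int = 6
    n_background_utrs: int = 10
    utr_length: int = 300
    motifs_per_target: int = 3
    frac_occupied: float = 0.5
    #: "designed" plants motifs in engineered accessible/stem contexts (the
    #: structure-assay scaffold); "neutral" plants them in plain random
    #: sequence (composition-sensitive sequence studies, e.g. k-mer discovery)
    motif_context: str = "designed"
    #: half-width of the A-rich accessible context around an occupied motif
    ss_protect_nt: int = 75
    #: inter-motif A-rich spacing inside one accessible block
    ss_spacer_nt: int = 25
    #: perfect-stem arm length hosting a paired-context motif
    stem_arm_nt: int = 12
    # --- sequencing --------------------------------------------------------
    read_depth: int = 100_000
    read_len: int = 130
    seq_error_rate: float = 0.002
    umi_length: int = 8
    replicates: int = 3
    rbns_replicates: int = 2
    # --- planted effects ---------------------------------------------------
    delta_lr_occupied: float = 4.0
    delta_lr_motif_only: float = 0.5
    affinity_scale: float = 3.0
    affinity_motif_only: float = 0.3
    # --- SLAM-seq ----------------------------------------------------------
    conversion_rate_labeled: float = 0.05
    background_conversion_rate: float = 0.001
    timepoints_h: Tuple[float, ...] = (0.0, 12.0)
    halflife_wt_h: float = 6.0
    halflife_ko_h: float = 12.0
    # --- RBNS --------------------------------------------------------------
    concentrations_nM: Tuple[float, ...] = (500.0, 50.0, 5.0)
    # --- fractionation RNA-seq ---------------------------------------------
    n_filler_genes: int = 200
    fractionation_base_mean: float = 2000.0
    fractionation_dispersion: float = 0.1
    #: expression of target genes relative to background (targets are a small
    #: share of the transcriptome, as in the real fractionation libraries)
    target_expr_factor: float = 0.05
    # --- CLIP --------------------------------------------------------------
    clip_fold: float = 3.5
    clip_read_rate_kb: float = 100.0
    clip_read_len: int = 30

    def validate(self) -> List[str]:
        errs = []
        for name in ("frac_occupied", "seq_error_rate", "conversion_rate_labeled",
                     "background_conversion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name} must be in [0, 1], got {v}")
        for name in ("n_target_utrs", "n_background_utrs", "utr_length",
                     "motifs_per_target", "read_depth", "read_len", "umi_length",
                     "replicates", "rbns_replicates", "n_filler_genes"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("halflife_wt_h", "halflife_ko_h"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be > 0, got {getattr(self, name)}")
        if self.replicates < 1:
            errs.append("replicates must be >= 1")
        if self.motif_context not in ("designed", "neutral"):
            errs.append(f"motif_context must be 'designed' or 'neutral', got {self.motif_context!r}")
        return errs

    def require_valid(self) -> "SimConfig":
        errs = self.validate()
        if errs:
            raise ValueError("invalid SimConfig: " + "; ".join(errs))
        return self


@dataclass
class PipelineConfig:
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    # pool design
    tile_len: int = 260
    tile_step: int = 6
    flank: int = 260
    max_utr_len: int = 10_000
    # localization
    pseudocount: float = 0.5
    rolling_window: int = 5
    test_method: str = "welch"
    # folding
    fold_window: int = 80
    fold_slide: int = 10
    # rbns
    min_input: int = 10
    # slam
    min_T: int = 200
    background_subtract: bool = False

    def __post_init__(self):
        self.sim.seed = self.seed


_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}
_TOP_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)} - {"sim"}


def validate_config(text: str) -> PipelineConfig:
    """Parse YAML text into a PipelineConfig.

    Collects *every* violation (unknown keys, type errors, out-of-range
    values) into one ValueError rather than stopping at the first.
    """
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is None:
        raw = {}
    errors: List[str] = []
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    top = {}
    sim_kw = {}
    for key, value in raw.items():
        if key == "sim":
            if not isinstance(value, dict):
                errors.append("sim block must be a mapping")
                continue
            for skey, sval in value.items():
                if skey not in _SIM_FIELDS:
                    errors.append(f"unknown key sim.{skey}")
                else:
                    sim_kw[skey] = tuple(sval) if isinstance(sval, list) else sval
        elif key in _TOP_FIELDS:
            top[key] = value
        elif key in _SIM_FIELDS:
            # convenience: flat sim keys accepted at top level
            sim_kw[key] = tuple(value) if isinstance(value, list) else value
        else:
            errors.append(f"unknown key {key}")
    try:
        sim = SimConfig(**sim_kw)
        errors.extend(sim.validate())
    except TypeError as err:
        errors.append(str(err))
        sim = SimConfig()
    try:
        cfg = PipelineConfig(sim=sim, **top)
    except TypeError as err:
        errors.append(str(err))
        cfg = PipelineConfig(sim=sim)
    if "seed" in top:
        cfg.sim.seed = cfg.seed
    elif "seed" in sim_kw:
        cfg.seed = sim.seed
        cfg.sim.seed = sim.seed
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return cfg


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        return validate_config(fh.read())


def dump_config(cfg: PipelineConfig) -> str:
    data = dataclasses.asdict(cfg)
    for key, value in list(data["sim"].items()):
        if isinstance(value, tuple):
            data["sim"][key] = list(value)
    return yaml.safe_dump(data, sort_keys=False)
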
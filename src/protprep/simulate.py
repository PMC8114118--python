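"""Synthetic protein-array experiments with known ground truth.

The generator emulates a KILchip-like forward-phase design: each slide
carries 21 mini-arrays (blocks), one serum sample per block; every
feature — antigens, control immunoglobulin spots, purification-tag
spots and printing-buffer spots — is printed in triplicate inside each
block.  Spot intensities follow the two-component error model

    fg = bg_spot + μ·e^η + ε,      η ~ N(0, ση²),  ε ~ N(0, σ²),

with the spot's own background bg drawn from a normal background field;
per-feature true signals μ are lognormal across features (spanning the
realistic MFI range and creating the usual mean–variance dependence),
with per-(feature, sample) biological variation on top.  Optional
slide/block log2 offsets, per-batch location/scale effects and tagged
antigens carrying additive anti-tag reactivity give every downstream
stage a recoverable ground truth.

Output is a set of ATF/GPR-style quantification files (one per slide),
plain-TSV layout files and a JSON ground-truth record — everything a
pipeline run needs, fully determined by the seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from protprep.io import ExperimentLayout, write_quantification_file

__all__ = ["SyntheticConfig", "SimulatedExperiment", "generate_experiment", "inject_artefact"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and noise parameters of a synthetic experiment.

    Defaults mirror the reference chip design: 21 mini-arrays per
    slide, one sample per block, features in triplicate, ~100 antigens
    plus IgG/IgM controls, three purification tags and buffer spots.
    Intensities are in arbitrary scanner units (16-bit scale).
    """

    n_slides: int = 2
    blocks_per_slide: int = 21
    n_features: int = 100  # antigens
    n_replicates: int = 3
    n_controls: int = 2  # e.g. IgG, IgM
    n_buffer: int = 2
    n_tags: int = 3  # e.g. GST, MBP, His
    tagged_fraction: float = 0.3
    block_cols: int = 12  # spot grid width within a block

    # background field (intensity units)
    bg_mean: float = 300.0
    bg_sd: float = 40.0

    # signal model
    log_mu_mean: float = np.log(1500.0)  # lognormal feature-level centre
    log_mu_sd: float = 1.2  # across-feature spread
    bio_sd: float = 0.5  # per-(feature, sample) biological variation, log scale
    eta_sd: float = 0.15  # multiplicative (proportional) noise sd
    eps_sd: float = 30.0  # additive noise sd
    control_mu: float = 20000.0
    tag_mu: float = 500.0
    tag_reactivity: float = 300.0  # additive anti-tag signal on tagged antigens

    # technical structure (log2 units / multiplicative)
    slide_effects: tuple[float, ...] = ()  # per-slide log2 offsets; default none
    block_effect_sd: float = 0.0  # log2 sd of block-position offsets
    batch_of_slide: tuple[str, ...] = ()  # batch label per slide; default all "b1"
    batch_shift: dict = field(default_factory=dict)  # batch → log2 location shift
    batch_scale: dict = field(default_factory=dict)  # batch → log scale factor

    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_slides", "blocks_per_slide", "n_features", "n_replicates", "block_cols"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.slide_effects and len(self.slide_effects) != self.n_slides:
            raise ValueError("slide_effects must have one entry per slide")
        if self.batch_of_slide and len(self.batch_of_slide) != self.n_slides:
            raise ValueError("batch_of_slide must have one entry per slide")

    @property
    def feature_names(self) -> dict[str, list[str]]:
        return {
            "antigen": [f"AG{i+1:03d}" for i in range(self.n_features)],
            "control": [f"CTRL{i+1}" for i in range(self.n_controls)],
            "tag": [f"TAG{i+1}" for i in range(self.n_tags)],
            "buffer": [f"BUF{i+1}" for i in range(self.n_buffer)],
        }


@dataclass
class SimulatedExperiment:
    """Generated files plus the in-memory tables and ground truth."""

    config: SyntheticConfig
    spots: pd.DataFrame  # slide, block, row, col, feature, fg, bg (+ per-spot truth)
    layout: ExperimentLayout
    truth: dict  # true_mu (feature × sample), effects, noise parameters
    out_dir: str | None = None
    gpr_paths: list[str] = field(default_factory=list)
    layout_paths: tuple[str, str] | None = None
    truth_path: str | None = None

    def write(self, out_dir: str) -> "SimulatedExperiment":
        os.makedirs(out_dir, exist_ok=True)
        self.out_dir = out_dir
        self.gpr_paths = []
        for slide, grp in self.spots.groupby("slide"):
            path = os.path.join(out_dir, f"{slide}.gpr")
            write_quantification_file(
                grp[["block", "row", "col", "feature", "fg", "bg"]],
                path,
                extra_headers={"Slide": str(slide)},
            )
            self.gpr_paths.append(path)
        fpath = os.path.join(out_dir, "features.tsv")
        bpath = os.path.join(out_dir, "blocks.tsv")
        self.layout.features.to_csv(fpath, sep="\t", index=False)
        self.layout.blocks.to_csv(bpath, sep="\t", index=False)
        self.layout_paths = (fpath, bpath)
        tpath = os.path.join(out_dir, "ground_truth.json")
        with open(tpath, "w") as fh:
            json.dump(_truth_jsonable(self.truth, self.config), fh, indent=1)
        self.truth_path = tpath
        return self


def _truth_jsonable(truth: dict, config: SyntheticConfig) -> dict:
    out = {"config": asdict(config)}
    for key, val in truth.items():
        if isinstance(val, pd.DataFrame):
            out[key] = {
                "index": list(map(str, val.index)),
                "columns": list(map(str, val.columns)),
                "values": np.round(val.to_numpy(float), 6).tolist(),
            }
        elif isinstance(val, pd.Series):
            out[key] = {str(k): float(v) for k, v in val.items()}
        else:
            out[key] = val
    return out


def generate_experiment(
    config: SyntheticConfig = SyntheticConfig(),
    out_dir: str | None = None,
) -> SimulatedExperiment:
    """Simulate a complete experiment; deterministic given config.seed.

    One sample per block; sample s of block j on slide i is named
    ``S<i>_<j>``.  Raises if the configured spot count does not fit the
    block grid (replicates × features exceeding capacity is a config
    error, not a silent truncation — the grid is derived, so this only
    triggers for non-positive geometry).
    """
    rng = np.random.default_rng(config.seed)
    names = config.feature_names
    printed = [(f, cls) for cls in ("antigen", "control", "tag", "buffer") for f in names[cls]]
    spots_per_block = len(printed) * config.n_replicates
    n_rows = int(np.ceil(spots_per_block / config.block_cols))
    if n_rows * config.block_cols < spots_per_block:
        raise ValueError("block grid cannot hold the configured features × replicates")

    slides = [f"slide{i+1}" for i in range(config.n_slides)]
    batch_of_slide = list(config.batch_of_slide) or ["b1"] * config.n_slides
    slide_fx = list(config.slide_effects) or [0.0] * config.n_slides
    block_fx = (
        rng.normal(0.0, config.block_effect_sd, size=config.blocks_per_slide)
        if config.block_effect_sd > 0
        else np.zeros(config.blocks_per_slide)
    )

    # feature-level true signals (log scale), shared across samples
    log_mu_feat = {
        f: rng.normal(config.log_mu_mean, config.log_mu_sd) for f in names["antigen"]
    }
    tagged = {}
    antigens = names["antigen"]
    n_tagged = int(round(config.tagged_fraction * len(antigens)))
    for i, f in enumerate(antigens[:n_tagged]):
        tagged[f] = names["tag"][i % config.n_tags] if config.n_tags else None

    samples, sample_slide, sample_block, sample_batch = [], {}, {}, {}
    for si, slide in enumerate(slides):
        for b in range(1, config.blocks_per_slide + 1):
            s = f"S{si+1}_{b}"
            samples.append(s)
            sample_slide[s] = slide
            sample_block[s] = b
            sample_batch[s] = batch_of_slide[si]

    # true per-(feature, sample) mean signal, technical effects included
    mu = pd.DataFrame(index=[f for f, _ in printed], columns=samples, dtype=float)
    base = pd.DataFrame(index=mu.index, columns=samples, dtype=float)  # biological truth
    for s in samples:
        si = slides.index(sample_slide[s])
        tech_log2 = slide_fx[si] + block_fx[sample_block[s] - 1]
        w = sample_batch[s]
        shift = config.batch_shift.get(w, 0.0)
        scale = config.batch_scale.get(w, 1.0)
        for f, cls in printed:
            if cls == "antigen":
                log_mu = log_mu_feat[f] + rng.normal(0.0, config.bio_sd)
            elif cls == "control":
                log_mu = np.log(config.control_mu)
            elif cls == "tag":
                log_mu = np.log(config.tag_mu)
            else:
                log_mu = -np.inf  # buffer: no analyte signal
            base.loc[f, s] = np.exp(log_mu) if np.isfinite(log_mu) else 0.0
            if np.isfinite(log_mu):
                log2_mu = log_mu / np.log(2.0)
                centred = log2_mu - config.log_mu_mean / np.log(2.0)
                log2_mu = config.log_mu_mean / np.log(2.0) + centred * scale + shift + tech_log2
                val = 2.0**log2_mu
            else:
                val = 0.0
            if cls == "antigen" and f in tagged and tagged[f]:
                val = val + config.tag_reactivity
            mu.loc[f, s] = val

    rows = []
    for si, slide in enumerate(slides):
        for b in range(1, config.blocks_per_slide + 1):
            s = f"S{si+1}_{b}"
            pos = 0
            for f, cls in printed:
                for _ in range(config.n_replicates):
                    r, c = divmod(pos, config.block_cols)
                    pos += 1
                    bg = max(rng.normal(config.bg_mean, config.bg_sd), 0.0)
                    m = mu.loc[f, s]
                    signal = (
                        m * np.exp(rng.normal(0.0, config.eta_sd)) + rng.normal(0.0, config.eps_sd)
                        if (m > 0 or config.eps_sd > 0)
                        else 0.0
                    )
                    rows.append(
                        {
                            "slide": slide,
                            "block": b,
                            "row": r + 1,
                            "col": c + 1,
                            "feature": f,
                            "fg": max(bg + signal, 0.0),
                            "bg": bg,
                        }
                    )
    spots = pd.DataFrame(rows)

    features = pd.DataFrame(
        [
            {"feature": f, "feature_class": cls, "tag_of": tagged.get(f)}
            for f, cls in printed
        ]
    )
    blocks = pd.DataFrame(
        [
            {"slide": sample_slide[s], "block": sample_block[s], "sample": s, "batch": sample_batch[s]}
            for s in samples
        ]
    )
    layout = ExperimentLayout(features=features, blocks=blocks)

    truth = {
        "true_mu": mu,
        "biological_mu": base,
        "slide_effects_log2": pd.Series(slide_fx, index=slides),
        "block_effects_log2": pd.Series(block_fx, index=range(1, config.blocks_per_slide + 1)),
        "batch_of_sample": sample_batch,
        "tagged_antigens": {k: v for k, v in tagged.items()},
        "eta_sd": config.eta_sd,
        "eps_sd": config.eps_sd,
        "artefact_blocks": [],
    }
    exp = SimulatedExperiment(config=config, spots=spots, layout=layout, truth=truth)
    if out_dir is not None:
        exp.write(out_dir)
    return exp


def inject_artefact(
    experiment: SimulatedExperiment,
    block_ids: list[tuple[str, int]],
    inflation: float,
    fraction: float = 0.8,
    seed: int = 0,
) -> SimulatedExperiment:
    """Inflate local-background medians in the listed blocks.

    Emulates a smear artefact confined to a mini-array, lying in the
    inter-spot regions where the scanner samples local background: a
    ``fraction`` of the block's spots (chosen reproducibly from
    ``seed``) get their *background* estimate multiplied by
    ``inflation`` while the spot foreground is untouched.  Plain local
    subtraction then over-subtracts at the affected spots, whereas the
    block minimum — anchored at the untouched minority — stays close
    to the true background field; this is exactly the situation the
    moving-minimum corrections exist for.  Files are rewritten when
    the experiment has an output directory; the ground truth records
    the affected blocks.

    ``inflation=1`` is the identity.
    """
    rng = np.random.default_rng(seed)
    spots = experiment.spots.copy()
    known = set(map(tuple, spots[["slide", "block"]].drop_duplicates().itertuples(index=False)))
    for sb in block_ids:
        if tuple(sb) not in known:
            raise ValueError(f"unknown (slide, block): {sb}")
    if inflation != 1.0:
        for slide, block in block_ids:
            idx = spots.index[(spots["slide"] == slide) & (spots["block"] == block)]
            n_hit = int(round(fraction * len(idx)))
            hit = rng.choice(idx, size=n_hit, replace=False)
            spots.loc[hit, "bg"] *= inflation
    out = SimulatedExperiment(
        config=experiment.config,
        spots=spots,
        layout=experiment.layout,
        truth={**experiment.truth, "artefact_blocks": [list(sb) for sb in block_ids] if inflation != 1.0 else []},
        out_dir=experiment.out_dir,
    )
    if experiment.out_dir is not None:
        out.write(experiment.out_dir)
    return out
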
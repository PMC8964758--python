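"""Synthetic breath-VOC cohort generator.

Emulates a GC–MS untargeted breathomics case/control study of hepatocellular
carcinoma (HCC): a samples × compounds peak-area table in arbitrary units
(AU), per-sample clinical metadata (group, BCLC stage, collection day,
pre/post-treatment pairing, responder status, treatment modality) and
per-day ambient-blank measurements.

The abundance model is log-normal: for sample *i* and compound *c*

    log2(AU_ic) = baseline_c + disease effect + day effect + N(0, noise_sd)

where the disease effect applies only to planted informative compounds in
HCC samples and is scaled by a nondecreasing per-stage gradient, giving
ground truth for stage-severity analyses. Non-detection is an exact zero
AU, independently per sample/compound with probability 1 − prevalence.
Ambient blanks are additive on the raw AU scale, so blank subtraction
recovers the endogenous signal exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "InformativeVOC",
    "TreatmentEffect",
    "SynthConfig",
    "SynthCohort",
    "generate_cohort",
    "write_cohort",
    "default_config",
    "STAGE_ORDER",
]

STAGE_ORDER = ("0", "A", "B", "C", "D")

#: Compound names drawn from breathomics practice; the generator pads with
#: voc_### placeholders past this list.
_NAMED_COMPOUNDS = (
    "Acetone",
    "1,4-Pentadiene",
    "Methylene chloride",
    "Benzene",
    "Phenol",
    "Allyl methyl sulfide",
    "D-Limonene",
    "Dimethyl sulfide",
    "Butane",
    "Acetic acid, methyl ester",
    "Cyclopentane",
    "Pentane",
    "1-Propene",
    "2-Pentanone",
    "Camphene",
    "Acetonitrile",
    "n-Hexane",
    "2-Butanone",
)


@dataclass(frozen=True)
class InformativeVOC:
    """A planted case/control effect on one compound.

    ``direction`` is +1 for elevated-in-HCC, −1 for depressed; ``effect`` is
    the base group-mean shift in log2 units, scaled per stage by
    :attr:`SynthConfig.stage_gradient`.
    """

    compound: int
    direction: int
    effect: float


@dataclass(frozen=True)
class TreatmentEffect:
    """Post−pre shift (raw AU scale) planted on one compound for treated patients."""

    compound: int
    responder_shift: float
    nonresponder_shift: float
    responder_sd: float = 0.0
    nonresponder_sd: float = 0.0


@dataclass(frozen=True)
class SynthConfig:
    """Full description of a synthetic cohort.

    Defaults mirror the study design this package targets: 97 HCC cases vs
    111 controls (78 cirrhosis, 33 healthy), BCLC stage mix 12/31/23/23/8,
    89 compounds of which 64 are prevalent, 34 treated patients with a 22/12
    responder split (TACE 20: 11 responders; PLAT 14: 11 responders).
    """

    n_healthy: int = 33
    n_cirrhosis: int = 78
    n_hcc: int = 97
    stage_weights: tuple[float, ...] = (12 / 97, 31 / 97, 23 / 97, 23 / 97, 8 / 97)
    n_voc: int = 89
    informative_voc: tuple[InformativeVOC, ...] = tuple(
        [InformativeVOC(i, +1 if i % 3 else -1, 1.5) for i in range(6)]
        + [InformativeVOC(6 + i, +1 if i % 2 else -1, 0.8) for i in range(12)]
    )
    stage_gradient: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5)
    prevalence: float | tuple[float, ...] = field(default=None)  # type: ignore[assignment]
    noise_sd: float = 0.75
    day_sd: float = 0.25
    ambient_level: float | tuple[float, ...] = 2e5
    n_days: int = 60
    n_treated: int = 34
    responder_fraction: float = 22 / 34
    modality_split: tuple[int, int] = (20, 14)  # (TACE, PLAT)
    responders_by_modality: tuple[int, int] | None = (11, 11)
    treatment_effects: tuple[TreatmentEffect, ...] = (
        TreatmentEffect(0, -73.38e6, -17.11e6, 56.76e6, 58.86e6),
        TreatmentEffect(7, +2.2e6, +0.3e6, 2.6e6, 0.9e6),
    )
    repeat_sd: float = 0.2
    baseline_overrides: tuple[tuple[int, float], ...] = ((0, 26.5), (7, 19.3))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prevalence is None:
            # 64 prevalent compounds out of 89 (rest below the 5% filter);
            # disease-relevant majors (acetone etc.) near-ubiquitous.
            n_major = min(18, self.n_voc)
            n_common = min(64, self.n_voc) - n_major
            prev = tuple([0.99] * n_major + [0.9] * n_common + [0.02] * max(0, self.n_voc - 64))
            object.__setattr__(self, "prevalence", prev)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if min(self.n_healthy, self.n_cirrhosis, self.n_hcc) < 0 or self.n_days < 1:
            raise ValueError("counts must be nonnegative and n_days >= 1")
        if abs(sum(self.stage_weights) - 1.0) > 1e-9:
            raise ValueError("stage_weights must sum to 1")
        if len(self.stage_weights) != len(STAGE_ORDER):
            raise ValueError("stage_weights must cover BCLC stages 0/A/B/C/D")
        if any(b < a - 1e-12 for a, b in zip(self.stage_gradient, self.stage_gradient[1:])):
            raise ValueError("stage_gradient must be nondecreasing")
        prev = np.atleast_1d(np.asarray(self.prevalence, dtype=float))
        if prev.size not in (1, self.n_voc):
            raise ValueError("prevalence must be scalar or length n_voc")
        if np.any((prev < 0) | (prev > 1)):
            raise ValueError("prevalence must lie in [0, 1]")
        for iv in self.informative_voc:
            if not 0 <= iv.compound < self.n_voc:
                raise ValueError(f"informative compound index {iv.compound} out of range")
        for te in self.treatment_effects:
            if not 0 <= te.compound < self.n_voc:
                raise ValueError(f"treatment compound index {te.compound} out of range")
        if self.n_treated > self.n_hcc:
            raise ValueError("n_treated cannot exceed n_hcc")
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if sum(self.modality_split) != self.n_treated:
            raise ValueError("modality_split must sum to n_treated")


@dataclass
class SynthCohort:
    """Generated cohort: peak table, metadata, blanks and planted ground truth."""

    voc_table: pd.DataFrame  # samples × compounds, raw AU (blanks included)
    meta: pd.DataFrame
    blanks: pd.DataFrame  # days × compounds, AU
    truth: dict

    @property
    def n_samples(self) -> int:
        return len(self.voc_table)


def default_config(**overrides) -> SynthConfig:
    """The study-sized default configuration, with keyword overrides.

    Constructed fresh (not via :func:`dataclasses.replace`) so the default
    prevalence vector tracks an overridden ``n_voc``.
    """
    if "informative_voc" in overrides:
        overrides["informative_voc"] = tuple(
            iv if isinstance(iv, InformativeVOC) else InformativeVOC(*iv)
            for iv in overrides["informative_voc"]
        )
    if "treatment_effects" in overrides:
        overrides["treatment_effects"] = tuple(
            te if isinstance(te, TreatmentEffect) else TreatmentEffect(*te)
            for te in overrides["treatment_effects"]
        )
    cfg = SynthConfig(**overrides)
    # default informative/treatment indices may exceed a small n_voc override
    if "informative_voc" not in overrides:
        cfg = replace(cfg, informative_voc=tuple(
            iv for iv in cfg.informative_voc if iv.compound < cfg.n_voc))
    if "treatment_effects" not in overrides:
        cfg = replace(cfg, treatment_effects=tuple(
            te for te in cfg.treatment_effects if te.compound < cfg.n_voc))
    return cfg


def _largest_remainder(weights: Sequence[float], total: int) -> np.ndarray:
    """Apportion ``total`` into integer counts proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    raw = w * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _compound_names(n: int) -> list[str]:
    names = list(_NAMED_COMPOUNDS[:n])
    names += [f"voc_{i:03d}" for i in range(len(names), n)]
    return names


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Draw one synthetic cohort from ``config``.

    Deterministic: identical config (including seed) gives bit-identical
    tables. Stage and responder counts are apportioned by largest remainder,
    so the default configuration reproduces the target stage mix exactly.
    """
    config.validate()
    rng = substream(config.seed, "cohort")

    n_voc = config.n_voc
    compounds = _compound_names(n_voc)
    groups = (
        ["healthy"] * config.n_healthy
        + ["cirrhosis"] * config.n_cirrhosis
        + ["hcc"] * config.n_hcc
    )
    n_pre = len(groups)

    # Stages for HCC samples: exact largest-remainder apportionment.
    stage_counts = _largest_remainder(config.stage_weights, config.n_hcc)
    hcc_stages = np.repeat(np.arange(len(STAGE_ORDER)), stage_counts)
    rng.shuffle(hcc_stages)

    stage_idx = np.full(n_pre, -1)
    stage_idx[np.asarray(groups) == "hcc"] = hcc_stages

    # Collection days: pre-treatment samples fill the first 80% of days
    # round-robin over a shuffled order (3–5 participants per day in the
    # study); post-treatment samples land on the remaining later days.
    n_pre_days = max(1, int(round(config.n_days * 0.8))) if config.n_treated else config.n_days
    order = rng.permutation(n_pre)
    days = np.empty(n_pre, dtype=int)
    days[order] = np.arange(n_pre) % n_pre_days

    # Per-compound baselines (log2 AU) and per-day batch effects.
    baseline = rng.uniform(17.0, 23.0, size=n_voc)
    for idx, val in config.baseline_overrides:
        if idx < n_voc:
            baseline[idx] = val
    day_effect = rng.normal(0.0, config.day_sd, size=(config.n_days, n_voc)) if config.day_sd > 0 else np.zeros((config.n_days, n_voc))

    # Planted disease effects, scaled by stage gradient for HCC samples.
    effect_vec = np.zeros(n_voc)
    for iv in config.informative_voc:
        effect_vec[iv.compound] += iv.direction * iv.effect
    gradient = np.asarray(config.stage_gradient)
    severity = np.where(stage_idx >= 0, gradient[np.clip(stage_idx, 0, None)], 0.0)

    log2_sig = (
        baseline[None, :]
        + severity[:, None] * effect_vec[None, :]
        + day_effect[days]
        + rng.normal(0.0, config.noise_sd, size=(n_pre, n_voc))
    )

    prev = np.broadcast_to(np.atleast_1d(np.asarray(config.prevalence, dtype=float)), (n_voc,))
    detected = rng.random((n_pre, n_voc)) < prev[None, :]
    endogenous = np.where(detected, np.exp2(log2_sig), 0.0)

    # Treated subset: pre/post pairing with planted responder-specific shifts.
    sample_ids = [f"S{i + 1:04d}" for i in range(n_pre)]
    hcc_positions = np.flatnonzero(np.asarray(groups) == "hcc")
    treated_pos = rng.choice(hcc_positions, size=config.n_treated, replace=False) if config.n_treated else np.array([], dtype=int)

    n_resp_total = int(round(config.responder_fraction * config.n_treated))
    modality = np.array(["TACE"] * config.modality_split[0] + ["PLAT"] * config.modality_split[1])
    if config.responders_by_modality is not None:
        if sum(config.responders_by_modality) != n_resp_total:
            raise ValueError("responders_by_modality must sum to the responder total")
        responder = np.concatenate(
            [
                np.array([True] * r + [False] * (m - r))
                for m, r in zip(config.modality_split, config.responders_by_modality)
            ]
        )
    else:
        responder = np.array([True] * n_resp_total + [False] * (config.n_treated - n_resp_total))
    perm = rng.permutation(config.n_treated)
    modality, responder = modality[perm], responder[perm]

    post_rows, post_ids, post_days, post_meta = [], [], [], []
    shift_by_compound = {te.compound: te for te in config.treatment_effects}
    for j, pos in enumerate(treated_pos):
        post_day = n_pre_days + (j % max(1, config.n_days - n_pre_days))
        post_day = min(post_day, config.n_days - 1)
        log2_post = log2_sig[pos] + rng.normal(0.0, config.repeat_sd, size=n_voc)
        post_au = np.where(detected[pos], np.exp2(log2_post), 0.0)
        for c, te in shift_by_compound.items():
            mu = te.responder_shift if responder[j] else te.nonresponder_shift
            sd = te.responder_sd if responder[j] else te.nonresponder_sd
            post_au[c] = max(post_au[c] + mu + (rng.normal(0.0, sd) if sd > 0 else 0.0), 0.0)
        post_rows.append(post_au)
        post_ids.append(f"{sample_ids[pos]}_post")
        post_days.append(post_day)
        post_meta.append((pos, j))

    # Ambient blanks, additive on the raw AU scale.
    amb = np.broadcast_to(np.atleast_1d(np.asarray(config.ambient_level, dtype=float)), (n_voc,))
    if np.any(amb > 0):
        blanks = amb[None, :] * np.exp(rng.normal(0.0, 0.25, size=(config.n_days, n_voc)))
        blanks = np.where(amb[None, :] > 0, blanks, 0.0)
    else:
        blanks = np.zeros((config.n_days, n_voc))

    all_ids = sample_ids + post_ids
    all_days = np.concatenate([days, np.asarray(post_days, dtype=int)]) if post_ids else days
    endo_all = np.vstack([endogenous] + [np.asarray(post_rows)]) if post_rows else endogenous
    measured = endo_all + blanks[all_days]

    voc_table = pd.DataFrame(measured, index=pd.Index(all_ids, name="sample_id"), columns=compounds)
    blanks_df = pd.DataFrame(blanks, index=pd.Index(range(config.n_days), name="day"), columns=compounds)

    pair_id = [""] * n_pre
    timepoint = [""] * n_pre
    resp_col = [""] * n_pre
    modality_col = [""] * n_pre
    for j, pos in enumerate(treated_pos):
        pair_id[pos] = f"P{j + 1:03d}"
        timepoint[pos] = "pre"
        resp_col[pos] = "yes" if responder[j] else "no"
        modality_col[pos] = modality[j]

    meta = pd.DataFrame(
        {
            "sample_id": all_ids,
            "group": groups + ["hcc"] * len(post_ids),
            "bclc_stage": [STAGE_ORDER[s] if s >= 0 else "" for s in stage_idx]
            + [STAGE_ORDER[stage_idx[pos]] for pos, _ in post_meta],
            "day": all_days,
            "pair_id": pair_id + [f"P{j + 1:03d}" for _, j in post_meta],
            "timepoint": timepoint + ["post"] * len(post_ids),
            "responder": resp_col + [("yes" if responder[j] else "no") for _, j in post_meta],
            "modality": modality_col + [modality[j] for _, j in post_meta],
        }
    )

    truth = {
        "informative": [iv.compound for iv in config.informative_voc],
        "informative_names": [compounds[iv.compound] for iv in config.informative_voc],
        "severity": severity,
        "responder": responder,
        "treated_sample_ids": [sample_ids[pos] for pos in treated_pos],
        "baseline_log2": baseline,
        "effect_log2": effect_vec,
    }
    return SynthCohort(voc_table=voc_table, meta=meta, blanks=blanks_df, truth=truth)


def write_cohort(cohort: SynthCohort, directory: str | Path) -> dict[str, Path]:
    """Write ``voc_table.csv``, ``meta.csv`` and ``blanks.csv`` to ``directory``.

    CSV, comma-delimited, UTF-8, header row; round-trips losslessly through
    the :mod:`breathvoc.preprocess` readers.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "voc_table": directory / "voc_table.csv",
            "meta": directory / "meta.csv",
            "blanks": directory / "blanks.csv",
        }
        cohort.voc_table.to_csv(paths["voc_table"], float_format="%.17g")
        cohort.meta.to_csv(paths["meta"], index=False)
        cohort.blanks.to_csv(paths["blanks"], float_format="%.17g")
    except OSError as exc:
        raise OSError(f"failed writing cohort files under {directory}: {exc}") from exc
    return paths
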
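"""Synthetic-world generator with planted structure for every pipeline stage.

A world emulates the data shape of a quantitative mitochondrial proteomics
study of mtDNA-depleted cells: an abundance-ratio table, reference
catalogs with an organelle annotation, a physical/functional link table
with confidence scores, flat term annotations, and a replicated two-
condition expression matrix with detection p-values.  The generator plants

* regulated functional modules (up- or down-regulated, with a small
  opposing fraction acting as negative regulators),
* a stochastic block model over the link table (dense within modules at
  ``p_in``, sparse elsewhere at ``p_out``; contaminants even sparser),
* confidence scores drawn from a high-skewed Beta within modules and a
  low-skewed Beta between,
* reference-catalog membership with per-set sensitivity for genuine
  mitochondrial proteins and a small false-positive rate for contaminants,
* a dominant annotation term per module, and
* per-module proteome-transcriptome concordance patterns: protein and
  mRNA both raised in up-modules, protein lowered but mRNA raised in
  down-modules (the compensatory transcription the depleted state evokes).

All randomness flows from one seeded generator, so a world is reproducible
bit-for-bit from its seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .core_model import DOWN, UNCHANGED, UP
from .concordance import DOWN_DOWN, DOWN_UP, RHO0, RHO_PLUS, UP_DOWN, UP_UP
from .reliability import FUNCTIONAL, PHYSICAL, ReferenceCatalog

CC_SET_NAME = "CC"


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of a synthetic study.

    Defaults mirror the structure of the emulated study: five up-regulated
    and eight down-regulated modules, a ~1.5-fold classification margin
    (log2 effect mean 1.0, sd 0.3), a 5% opposing fraction inside modules,
    a large unchanged background, and a contaminant pool that is never
    referenced and only sparsely linked.
    """

    seed: int
    n_up_modules: int = 5
    n_down_modules: int = 8
    module_size: int = 20
    opposing_fraction: float = 0.05
    effect_log2_mean: float = 1.0
    effect_log2_sd: float = 0.3
    background_log2_sd: float = 0.2
    n_background: int = 400
    n_contaminants: int = 150
    p_in: float = 0.3
    p_out: float = 0.01
    p_contaminant: float = 0.0005
    conf_within: Tuple[float, float] = (8.0, 2.0)
    conf_between: Tuple[float, float] = (2.0, 8.0)
    physical_fraction: float = 0.3
    n_reference_sets: int = 13
    reference_sensitivity: float = 0.5
    reference_fpr: float = 0.02
    cc_sensitivity: float = 0.9
    cc_fpr: float = 0.02
    dominant_term_fraction: float = 0.8
    n_background_terms: int = 30
    background_term_prob: float = 0.05
    mrna_effect_log2: float = 1.0
    mrna_noise_sd: float = 0.3
    n_replicates: int = 3
    base_log2_mean: float = 7.0
    base_log2_sd: float = 1.0
    undetected_fraction: float = 0.05
    # how non-module (background) proteins scatter over the joint
    # protein/mRNA concordance patterns; order: unchanged, up_up,
    # down_down, up_down, down_up
    background_group_fractions: Tuple[float, float, float, float, float] = (
        0.60,
        0.08,
        0.12,
        0.08,
        0.12,
    )

    def __post_init__(self) -> None:
        probs = (
            self.opposing_fraction,
            self.p_in,
            self.p_out,
            self.p_contaminant,
            self.physical_fraction,
            self.reference_sensitivity,
            self.reference_fpr,
            self.cc_sensitivity,
            self.cc_fpr,
            self.dominant_term_fraction,
            self.background_term_prob,
            self.undetected_fraction,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.background_group_fractions) - 1.0) > 1e-9:
            raise ValueError("background_group_fractions must sum to 1")
        if min(self.n_up_modules, self.n_down_modules) < 0 or self.module_size < 1:
            raise ValueError("module counts and sizes must be positive")
        if self.p_in < self.p_out:
            import warnings

            warnings.warn(
                "p_in < p_out: planted modules will not be recoverable", stacklevel=2
            )

    @property
    def n_modules(self) -> int:
        return self.n_up_modules + self.n_down_modules


@dataclass
class World:
    """All generated tables plus the planted ground truth."""

    config: WorldConfig
    truth: pd.DataFrame
    abundance: pd.DataFrame
    catalog: ReferenceCatalog
    links: pd.DataFrame
    annotations: pd.DataFrame
    intensities: pd.DataFrame
    detection_p: pd.DataFrame
    conditions: Dict[str, str]

    def annotation_map(self) -> Dict[str, frozenset]:
        out: Dict[str, set] = {}
        for pid, term in zip(self.annotations["protein_id"], self.annotations["term_id"]):
            out.setdefault(pid, set()).add(term)
        return {p: frozenset(t) for p, t in out.items()}


def _concordance_group(protein_sign: int, mrna_sign: int) -> str:
    if protein_sign > 0 and mrna_sign > 0:
        return UP_UP
    if protein_sign < 0 and mrna_sign < 0:
        return DOWN_DOWN
    if protein_sign > 0 and mrna_sign < 0:
        return UP_DOWN
    if protein_sign < 0 and mrna_sign > 0:
        return DOWN_UP
    return UNCHANGED


def generate_world(config: WorldConfig) -> World:
    """Draw one synthetic study from a :class:`WorldConfig`.

    Deterministic given ``config.seed``: two calls with equal configs
    produce identical tables.
    """
    rng = np.random.default_rng(config.seed)

    # --- protein universe -------------------------------------------------
    module_ids: List[str] = [f"M{i + 1:02d}" for i in range(config.n_modules)]
    module_pattern = {
        mid: (UP if i < config.n_up_modules else DOWN)
        for i, mid in enumerate(module_ids)
    }
    records = []  # protein_id, module_id, planted_class, mrna_sign, kind
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"P{counter:04d}"

    for mid in module_ids:
        pattern = module_pattern[mid]
        for _ in range(config.module_size):
            pid = next_id()
            opposing = rng.random() < config.opposing_fraction
            planted = (DOWN if pattern == UP else UP) if opposing else pattern
            # mRNA rises in both module kinds (compensatory transcription);
            # opposing members follow their own protein direction.
            mrna_sign = 1
            prot_sign = 1 if planted == UP else -1
            records.append((pid, mid, planted, prot_sign, mrna_sign, "module"))
    # background proteins scatter over the concordance patterns: sign pairs
    # in the order (unchanged, up_up, down_down, up_down, down_up)
    group_signs = ((0, 0), (1, 1), (-1, -1), (1, -1), (-1, 1))
    for _ in range(config.n_background):
        which = rng.choice(5, p=config.background_group_fractions)
        prot_sign, mrna_sign = group_signs[which]
        planted = UP if prot_sign > 0 else DOWN if prot_sign < 0 else UNCHANGED
        records.append((next_id(), "", planted, prot_sign, mrna_sign, "background"))
    for _ in range(config.n_contaminants):
        records.append((next_id(), "", UNCHANGED, 0, 0, "contaminant"))

    truth = pd.DataFrame(
        records,
        columns=["protein_id", "module_id", "planted_class", "prot_sign", "mrna_sign", "kind"],
    )
    truth["referenced"] = truth["kind"] != "contaminant"
    truth["concordance_group"] = [
        _concordance_group(ps, ms) for ps, ms in zip(truth["prot_sign"], truth["mrna_sign"])
    ]

    ids = list(truth["protein_id"])
    n = len(ids)
    kind = truth["kind"].to_numpy()
    module_of = dict(zip(truth["protein_id"], truth["module_id"]))

    # --- abundance ratios -------------------------------------------------
    log2_ratio = np.empty(n)
    for i, (sign, k) in enumerate(zip(truth["prot_sign"], kind)):
        if sign != 0:
            log2_ratio[i] = sign * rng.normal(
                config.effect_log2_mean, config.effect_log2_sd
            )
        else:
            log2_ratio[i] = rng.normal(0.0, config.background_log2_sd)
    abundance = pd.DataFrame(
        {"protein_id": ids, "protein_ratio": np.power(2.0, log2_ratio)}
    )

    # --- link table (stochastic block model) ------------------------------
    rows = []
    mods = truth["module_id"].to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            same_module = mods[i] != "" and mods[i] == mods[j]
            if same_module:
                p_edge, beta = config.p_in, config.conf_within
            elif kind[i] == "contaminant" or kind[j] == "contaminant":
                p_edge, beta = config.p_contaminant, config.conf_between
            else:
                p_edge, beta = config.p_out, config.conf_between
            if rng.random() < p_edge:
                conf = float(np.clip(rng.beta(*beta), 0.0, 1.0))
                channel = (
                    PHYSICAL if rng.random() < config.physical_fraction else FUNCTIONAL
                )
                rows.append((ids[i], ids[j], conf, channel))
    links = pd.DataFrame(
        rows, columns=["protein_a", "protein_b", "confidence", "channel"]
    )

    # --- reference catalog ------------------------------------------------
    genuine = truth["referenced"].to_numpy()
    cc_mask = np.where(
        genuine,
        rng.random(n) < config.cc_sensitivity,
        rng.random(n) < config.cc_fpr,
    )
    reference_sets = {}
    for s in range(config.n_reference_sets):
        mask = np.where(
            genuine,
            rng.random(n) < config.reference_sensitivity,
            rng.random(n) < config.reference_fpr,
        )
        reference_sets[f"REF{s + 1:02d}"] = frozenset(np.array(ids)[mask])
    catalog = ReferenceCatalog(
        cc_annotated=frozenset(np.array(ids)[cc_mask]),
        reference_sets=reference_sets,
    )

    # --- annotations ------------------------------------------------------
    ann_rows = []
    for pid in ids:
        mid = module_of[pid]
        if mid and rng.random() < config.dominant_term_fraction:
            ann_rows.append((pid, f"T_{mid}"))
        for t in range(config.n_background_terms):
            if rng.random() < config.background_term_prob:
                ann_rows.append((pid, f"BG{t + 1:02d}"))
    annotations = pd.DataFrame(ann_rows, columns=["protein_id", "term_id"])

    # --- expression matrix ------------------------------------------------
    samples = [f"{RHO0}_{r + 1}" for r in range(config.n_replicates)] + [
        f"{RHO_PLUS}_{r + 1}" for r in range(config.n_replicates)
    ]
    conditions = {
        s: (RHO0 if s.startswith(RHO0) else RHO_PLUS) for s in samples
    }
    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n)
    mrna_effect = truth["mrna_sign"].to_numpy() * config.mrna_effect_log2
    log_intens = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        shift = mrna_effect if conditions[s] == RHO0 else 0.0
        log_intens[:, j] = base + shift + rng.normal(0.0, config.mrna_noise_sd, size=n)
    intensities = pd.DataFrame(
        np.power(2.0, log_intens), index=ids, columns=samples
    )
    intensities.index.name = "gene_id"

    # undetected genes drawn from the non-module pool so planted modules
    # keep complete expression profiles
    non_module = truth.index[truth["module_id"] == ""].to_numpy()
    n_undetected = int(round(config.undetected_fraction * len(non_module)))
    undetected_idx = set(
        rng.choice(non_module, size=n_undetected, replace=False).tolist()
        if n_undetected
        else []
    )
    det = rng.uniform(0.0, 0.04, size=(n, len(samples)))
    for i in undetected_idx:
        det[i, :] = rng.uniform(0.2, 1.0, size=len(samples))
    detection_p = pd.DataFrame(det, index=ids, columns=samples)
    detection_p.index.name = "gene_id"
    truth["undetected"] = [i in undetected_idx for i in range(n)]

    truth = truth.drop(columns=["prot_sign", "mrna_sign"])
    return World(
        config=config,
        truth=truth,
        abundance=abundance,
        catalog=catalog,
        links=links,
        annotations=annotations,
        intensities=intensities,
        detection_p=detection_p,
        conditions=conditions,
    )


def world_summary(truth: pd.DataFrame) -> pd.DataFrame:
    """Planted counts per class, module, and concordance group."""
    rows = []
    for cls, cnt in truth["planted_class"].value_counts().items():
        rows.append(("class", cls, int(cnt)))
    for mid, cnt in truth.loc[truth["module_id"] != "", "module_id"].value_counts().sort_index().items():
        rows.append(("module", mid, int(cnt)))
    for grp, cnt in truth["concordance_group"].value_counts().items():
        rows.append(("concordance_group", grp, int(cnt)))
    for k, cnt in truth["kind"].value_counts().items():
        rows.append(("kind", k, int(cnt)))
    return pd.DataFrame(rows, columns=["facet", "label", "count"])
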
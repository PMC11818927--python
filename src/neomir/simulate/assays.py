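"""Simulated wet-lab validation data.

Ct tables are constructed by inversion of the 2^-ddCt method, so that with
zero noise the downstream relative-quantification recovers the programmed
fold changes exactly; luciferase wells carry programmed firefly/Renilla
treatment ratios; glucose-production wells carry per-well protein content;
and the neonatal blood-glucose time series follows the fall-then-rebound
trajectory (6.03 mmol/L at birth, nadir 1.23 mmol/L at 3 h, 2.23 mmol/L at
6 h) with configurable measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from ..containers import TruthTables
from .config import SyntheticConfig
from .reference import MIR_22_3P_ID

#: blood glucose anchors: (hours after birth, mmol/L)
BLOOD_GLUCOSE_ANCHORS = ((0.0, 6.03), (3.0, 1.23), (6.0, 2.23))

#: default postnatal-vs-prenatal qPCR fold changes (liver axis)
DEFAULT_QPCR_FOLDS = {
    MIR_22_3P_ID: 4.0,
    "AKT3": 0.5,
    "FoxO1": 2.0,
    "PCK1": 3.0,
    "G6PC": 2.5,
}

#: firefly/Renilla treatment ratio relative to mimic control
DEFAULT_LUCIFERASE_RATIOS = {
    ("Wt", "mimic"): 0.55,
    ("Wt", "mimic_control"): 1.0,
    ("Mut", "mimic"): 1.0,
    ("Mut", "mimic_control"): 1.0,
}

#: relative glucose output per transfection group
DEFAULT_GLUCOSE_EFFECTS = {"mimic_control": 1.0, "mimic": 1.4, "inhibitor": 0.7}


@dataclass
class AssayData:
    ct: pd.DataFrame
    luciferase: pd.DataFrame
    glucose: pd.DataFrame
    blood_glucose: pd.DataFrame


def simulate_assays(
    truth: TruthTables | None,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    fold_changes: dict[str, float] | None = None,
    n_reps: int = 3,
) -> AssayData:
    """Generate Ct, luciferase, glucose-production and blood-glucose tables.

    When the truth tables carry a planted liver miR-22-3p stage effect, its
    fold change overrides the default qPCR programme.
    """
    if rng is None:
        rng = config.rng(3)
    folds = dict(DEFAULT_QPCR_FOLDS if fold_changes is None else fold_changes)
    if truth is not None and (MIR_22_3P_ID, "liver") in truth.true_de:
        folds[MIR_22_3P_ID] = float(2.0 ** truth.true_de[(MIR_22_3P_ID, "liver")])
    bad = [g for g, f in folds.items() if not f > 0]
    if bad:
        raise ValueError(f"non-positive fold change for {bad[0]!r}")

    sd = config.ct_noise_sd

    # -- qPCR Ct table ------------------------------------------------------
    rows = []
    for gene, fold in folds.items():
        is_mirna = "miR" in gene or gene.startswith("syn-")
        ref_gene = "U6" if is_mirna else "GAPDH"
        base = float(rng.uniform(3.0, 8.0))  # target minus reference offset
        for group, expr in (("prenatal", 1.0), ("postnatal", fold)):
            for rep in range(1, n_reps + 1):
                ref_ct = 20.0 + rng.normal(0.0, sd)
                target_ct = ref_ct + base - np.log2(expr) + rng.normal(0.0, sd)
                rows.append((f"{group}_{rep}", group, gene, target_ct,
                             ref_gene, ref_ct))
    ct = pd.DataFrame(rows, columns=["sample_id", "group", "target_gene",
                                     "target_ct", "reference_gene",
                                     "reference_ct"])

    # -- dual-luciferase wells ---------------------------------------------
    rows = []
    for (construct, treatment), ratio in DEFAULT_LUCIFERASE_RATIOS.items():
        base = float(rng.uniform(0.8, 1.2))
        for rep in range(1, n_reps + 1):
            renilla = float(rng.lognormal(np.log(1e5), 0.1))
            firefly = renilla * base * ratio * float(rng.lognormal(0.0, 0.05))
            rows.append((construct, treatment, rep, firefly, renilla))
    luciferase = pd.DataFrame(rows, columns=["construct", "treatment",
                                             "replicate", "firefly", "renilla"])

    # -- glucose production -------------------------------------------------
    rows = []
    for group, effect in DEFAULT_GLUCOSE_EFFECTS.items():
        for rep in range(1, n_reps + 1):
            protein = float(np.clip(rng.normal(1.0, 0.05), 0.5, None))
            glucose = 10.0 * effect * protein * float(rng.lognormal(0.0, 0.05))
            rows.append((group, rep, glucose, protein))
    glucose = pd.DataFrame(rows, columns=["group", "replicate",
                                          "glucose_raw", "protein"])

    # -- neonatal blood-glucose time series ---------------------------------
    anchors = np.array(BLOOD_GLUCOSE_ANCHORS)
    curve = PchipInterpolator(anchors[:, 0], anchors[:, 1])
    hours = np.arange(0.0, 6.5, 0.5)
    values = {
        f"piglet_{k}": np.clip(
            curve(hours) + rng.normal(0.0, config.glucose_noise_sd, len(hours)),
            0.1, None,
        )
        for k in range(1, 4)
    }
    blood = pd.DataFrame(values, index=pd.Index(hours, name="hours_after_birth"))

    return AssayData(ct=ct, luciferase=luciferase, glucose=glucose,
                     blood_glucose=blood)
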
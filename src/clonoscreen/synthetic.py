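"""Synthetic assay generators with known ground truth.

Every assay the analysis pipeline consumes can be emulated here: the 96-well
clonogenic screen (Poisson colony counts under drug x radiation survival),
CCK-8 viability curves, two-channel Annexin/PI event clouds, propidium-iodide
DNA-content histograms, and caliper-measured xenograft growth. Each generator
returns a tidy :class:`pandas.DataFrame` plus a :class:`GroundTruth` record of
the exact parameters used, so parameter-recovery tests can compare pipeline
estimates against truth.

Model summary for the screen: a well seeded with ``n`` cells at plating
efficiency ``PE`` forms colonies as ``Poisson(n * PE * S)`` where the survival
term ``S`` factorises as

* drug alone:      ``S_drug(x) = 1 / (1 + (x / IC50)**h)``   (Hill survival)
* radiation alone: ``S_IR(D)  = exp(-(alpha*D + beta*D**2))`` (linear-quadratic)
* combination:     ``S_drug(x) * exp(-f * (alpha*D + beta*D**2))``

``f`` is the radiosensitization factor: ``f = 1`` means the drug and radiation
act independently (multiplicatively), so the expected survival-reduction
factor SRF equals 1; ``f > 1`` inflates radiation log-kill in the presence of
drug and yields SRF = S_IR ** (1 - f) > 1 at every detectable concentration.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScreenGenConfig",
    "GroundTruth",
    "simulate_screen",
    "expected_srf",
    "simulate_cck8",
    "simulate_flow_apoptosis",
    "simulate_flow_cellcycle",
    "simulate_growth",
    "DEFAULT_LADDER",
]

#: Ten-fold concentration ladder, 10 uM down to 10 pM (molar).
DEFAULT_LADDER: tuple[float, ...] = (1e-5, 1e-6, 1e-7, 1e-8, 1e-9, 1e-10, 1e-11)

#: Fixed caliper aspect ratio used to back-solve (L, W) from a volume.
CALIPER_ASPECT_RATIO = 1.25


@dataclass
class GroundTruth:
    """Generator parameters echoed alongside a synthetic dataset.

    ``assay`` names the generator; ``params`` holds every parameter it used,
    in plain scalars/lists so the record round-trips losslessly through YAML.
    """

    assay: str
    params: dict

    def to_yaml(self) -> str:
        return yaml.safe_dump({"assay": self.assay, "params": self.params},
                              sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "GroundTruth":
        d = yaml.safe_load(io.StringIO(text))
        return cls(assay=d["assay"], params=d["params"])


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


@dataclass
class ScreenGenConfig:
    """Design of one simulated high-content clonogenic screen plate.

    Defaults mirror the screen design: 50 cells per well in triplicate, seven
    ten-fold concentrations from 10 uM to 10 pM, a single 2 Gy radiation arm.
    ``sensitization_factor`` may be a scalar (applied at every concentration)
    or a per-concentration sequence aligned with ``concentration_ladder``.
    ``overdispersion`` switches colony counts from Poisson to negative
    binomial with that dispersion (variance = mu + mu^2/overdispersion).
    """

    cells_seeded_per_well: int = 50
    replicates: int = 3
    concentration_ladder: tuple[float, ...] = DEFAULT_LADDER
    radiation_dose: float = 2.0
    plating_efficiency: float = 0.8
    drug_ic50: float = 1e-9
    drug_hill: float = 2.0
    lq_alpha: float = 0.3
    lq_beta: float = 0.03
    sensitization_factor: float | tuple[float, ...] = 1.0
    overdispersion: float | None = None
    drug_id: str = "drug"
    plate_id: str = "P1"
    seed: int = 0

    def __post_init__(self) -> None:
        ladder = tuple(float(c) for c in self.concentration_ladder)
        if len(ladder) == 0:
            raise ValueError("concentration ladder is empty")
        if any(c <= 0 for c in ladder):
            raise ValueError("concentrations must be positive (molar)")
        if any(b >= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("concentration ladder must be strictly decreasing")
        self.concentration_ladder = ladder
        if not (0.0 < self.plating_efficiency <= 1.0):
            raise ValueError("plating_efficiency must lie in (0, 1]")
        for name in ("radiation_dose", "drug_ic50", "drug_hill",
                     "lq_alpha", "lq_beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        f = self.sensitization_factor
        fs = (f,) if np.isscalar(f) else tuple(float(v) for v in f)
        if not np.isscalar(f) and len(fs) != len(ladder):
            raise ValueError("per-concentration sensitization_factor must "
                             "match the ladder length")
        if any(v < 0 for v in fs):
            raise ValueError("sensitization_factor must be >= 0")
        if self.cells_seeded_per_well <= 0 or self.replicates <= 0:
            raise ValueError("cells_seeded_per_well and replicates must be >= 1")

    # -- survival terms -----------------------------------------------------

    def sensitization_at(self, conc_index: int) -> float:
        f = self.sensitization_factor
        return float(f) if np.isscalar(f) else float(f[conc_index])

    def drug_survival(self, concentration: float) -> float:
        """Hill survival term S_drug(x) = 1 / (1 + (x/IC50)^h)."""
        if self.drug_ic50 == 0:
            return 0.0
        return 1.0 / (1.0 + (concentration / self.drug_ic50) ** self.drug_hill)

    def ir_log_kill(self) -> float:
        """alpha*D + beta*D^2 at the screen's radiation dose."""
        d = self.radiation_dose
        return self.lq_alpha * d + self.lq_beta * d * d

    def ir_survival(self) -> float:
        return float(np.exp(-self.ir_log_kill()))

    def ground_truth(self) -> GroundTruth:
        params = asdict(self)
        params["concentration_ladder"] = list(self.concentration_ladder)
        if not np.isscalar(params["sensitization_factor"]):
            params["sensitization_factor"] = list(params["sensitization_factor"])
        return GroundTruth(assay="screen", params=params)


def expected_srf(config: ScreenGenConfig) -> np.ndarray:
    """Analytic expected SRF at each ladder concentration.

    Because the drug term cancels, SRF = S_IR ** (1 - f); with f = 1 the
    expected SRF is exactly 1 at every concentration.
    """
    s_ir = config.ir_survival()
    fs = np.array([config.sensitization_at(i)
                   for i in range(len(config.concentration_ladder))])
    return s_ir ** (1.0 - fs)


def _draw_counts(rng: np.random.Generator, mean: float, size: int,
                 overdispersion: float | None) -> np.ndarray:
    if not np.isfinite(mean) or mean < 0:
        raise ValueError(f"non-finite or negative expected colony count: {mean}")
    if overdispersion is None:
        return rng.poisson(mean, size=size)
    if mean == 0:
        return np.zeros(size, dtype=int)
    k = overdispersion
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=size)


def simulate_screen(config: ScreenGenConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one screen plate as a long-format well table.

    Conditions generated, each in ``config.replicates`` wells: untreated
    control, radiation alone, drug alone at every ladder concentration, and
    drug + radiation at every ladder concentration. Columns: ``plate_id,
    well, drug_id, concentration, radiation_dose, replicate, colony_count``
    (concentration is NaN for control / radiation-only wells).
    """
    rng = _rng(config.seed)
    base = config.cells_seeded_per_well * config.plating_efficiency
    s_ir_logkill = config.ir_log_kill()

    conditions: list[tuple[float, float, float]] = []  # (conc, dose, mean)
    conditions.append((np.nan, 0.0, base))
    conditions.append((np.nan, config.radiation_dose,
                       base * np.exp(-s_ir_logkill)))
    for i, x in enumerate(config.concentration_ladder):
        sd = config.drug_survival(x)
        conditions.append((x, 0.0, base * sd))
        f = config.sensitization_at(i)
        conditions.append((x, config.radiation_dose,
                           base * sd * np.exp(-f * s_ir_logkill)))

    rows = []
    well_no = 0
    for conc, dose, mean in conditions:
        counts = _draw_counts(rng, mean, config.replicates,
                              config.overdispersion)
        for rep, c in enumerate(counts):
            row, col = divmod(well_no, 12)
            rows.append({
                "plate_id": config.plate_id,
                "well": f"{chr(ord('A') + row % 8)}{col + 1}",
                "drug_id": config.drug_id if np.isfinite(conc) else "",
                "concentration": conc,
                "radiation_dose": dose,
                "replicate": rep,
                "colony_count": int(c),
            })
            well_no += 1
    return pd.DataFrame(rows), config.ground_truth()


def simulate_cck8(ic50: float, hill: float, doses: Sequence[float],
                  noise_sd: float, replicates: int, seed: int,
                  ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a CCK-8 dose-viability table.

    Viability follows the logistic decay ``1 / (1 + (d/IC50)^h)`` with
    additive Gaussian noise of SD ``noise_sd``, clipped to [0, 1.2]
    (absorbance ratios can mildly exceed 1). Columns: dose, replicate,
    viability.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed)
    with np.errstate(over="ignore"):
        clean = 1.0 / (1.0 + (doses / ic50) ** hill)
    rows = []
    for rep in range(replicates):
        noisy = np.clip(clean + rng.normal(0.0, noise_sd, size=doses.size),
                        0.0, 1.2)
        for d, v in zip(doses, noisy):
            rows.append({"dose": d, "replicate": rep, "viability": v})
    gt = GroundTruth("cck8", {"ic50": float(ic50), "hill": float(hill),
                              "doses": [float(d) for d in doses],
                              "noise_sd": float(noise_sd),
                              "replicates": int(replicates),
                              "seed": int(seed)})
    return pd.DataFrame(rows), gt


# Default log10 intensity centres for the four Annexin/PI populations:
# (annexin, PI) for viable, early-apoptotic, late-apoptotic, necrotic.
_APO_CENTERS = {
    "viable": (1.0, 1.0),
    "early": (2.5, 1.0),
    "late": (2.5, 2.5),
    "necrotic": (1.0, 2.5),
}
_APO_ORDER = ("viable", "early", "late", "necrotic")


def simulate_flow_apoptosis(fractions: Sequence[float], n_events: int,
                            seed: int, log_sd: float = 0.25,
                            ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate an Annexin V-FITC / PI event table.

    Events are drawn from four bivariate log-normal clusters (viable,
    early-apoptotic, late-apoptotic, necrotic) with mixing weights
    ``fractions`` in that order. Columns: annexin, pi, population (the
    true label, for oracle tests).
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (4,):
        raise ValueError("fractions must be a 4-vector "
                         "(viable, early, late, necrotic)")
    if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be nonnegative and sum to 1")
    rng = _rng(seed)
    labels = rng.choice(4, size=n_events, p=fr)
    ann = np.empty(n_events)
    pi = np.empty(n_events)
    for k, name in enumerate(_APO_ORDER):
        mask = labels == k
        ca, cp = _APO_CENTERS[name]
        ann[mask] = 10.0 ** rng.normal(ca, log_sd, mask.sum())
        pi[mask] = 10.0 ** rng.normal(cp, log_sd, mask.sum())
    df = pd.DataFrame({"annexin": ann, "pi": pi,
                       "population": [_APO_ORDER[k] for k in labels]})
    gt = GroundTruth("flow_apoptosis", {
        "fractions": [float(f) for f in fr], "n_events": int(n_events),
        "log_sd": float(log_sd), "seed": int(seed),
        "apoptotic_fraction": float(fr[1] + fr[2])})
    return df, gt


def simulate_flow_cellcycle(fractions: Sequence[float], n_events: int,
                            cv: float, seed: int, g1_mean: float = 100.0,
                            ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a one-channel PI DNA-content event table.

    G0/G1 events are Gaussian at the 2N position ``g1_mean`` with SD
    ``cv * g1_mean``; G2/M events are Gaussian at exactly twice the G1 mean
    with SD ``cv * 2 * g1_mean``; S-phase events are uniform between the two
    peaks plus the same Gaussian smear as G1 (a broadened bridge).
    ``fractions`` orders as (G0/G1, S, G2/M). Columns: dna_content, phase.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,):
        raise ValueError("fractions must be a 3-vector (G0/G1, S, G2/M)")
    if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be nonnegative and sum to 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = _rng(seed)
    labels = rng.choice(3, size=n_events, p=fr)
    x = np.empty(n_events)
    g1 = labels == 0
    s = labels == 1
    g2 = labels == 2
    x[g1] = rng.normal(g1_mean, cv * g1_mean, g1.sum())
    x[g2] = rng.normal(2 * g1_mean, cv * 2 * g1_mean, g2.sum())
    x[s] = (rng.uniform(g1_mean, 2 * g1_mean, s.sum())
            + rng.normal(0.0, cv * g1_mean, s.sum()))
    phases = np.array(["G0/G1", "S", "G2/M"])[labels]
    df = pd.DataFrame({"dna_content": x, "phase": phases})
    gt = GroundTruth("flow_cellcycle", {
        "fractions": [float(f) for f in fr], "n_events": int(n_events),
        "cv": float(cv), "g1_mean": float(g1_mean), "seed": int(seed)})
    return df, gt


_DEFAULT_GROUP_NAMES = ("PBS", "drug", "IR", "drug+IR")


def simulate_growth(groups: Sequence[tuple[float, int]], v0: float,
                    growth_rate: float, days: Sequence[float],
                    noise_cv: float, seed: int,
                    aspect_ratio: float = CALIPER_ASPECT_RATIO,
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate xenograft caliper trajectories.

    Each group is ``(effect_multiplier, n_mice)``; tumor volume follows
    ``v0 * exp(effect * growth_rate * t)`` with multiplicative log-normal
    noise of coefficient of variation ``noise_cv`` (median-preserving:
    volume is multiplied by ``exp(N(0, sigma))``). Caliper length L and
    width W are back-solved with a fixed aspect ratio ``phi = L/W`` so that
    ``(pi/6) * L * W**2`` reproduces the noisy volume exactly. Columns:
    mouse_id, group, day, length_mm, width_mm, volume_mm3.
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = _rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    names = (_DEFAULT_GROUP_NAMES if len(groups) == 4
             else tuple(f"g{i + 1}" for i in range(len(groups))))
    rows = []
    mouse_no = 0
    for (mult, n_mice), name in zip(groups, names):
        for _ in range(n_mice):
            mouse_no += 1
            for t in days:
                v = v0 * np.exp(mult * growth_rate * t)
                if sigma > 0:
                    v *= np.exp(rng.normal(0.0, sigma))
                # V = (pi/6) L W^2 with W = L/phi  =>  L = (6 V phi^2/pi)^(1/3)
                length = (6.0 * v * aspect_ratio ** 2 / np.pi) ** (1.0 / 3.0)
                width = length / aspect_ratio
                rows.append({"mouse_id": f"m{mouse_no:03d}", "group": name,
                             "day": float(t), "length_mm": length,
                             "width_mm": width, "volume_mm3": v})
    gt = GroundTruth("growth", {
        "groups": [[float(m), int(n)] for m, n in groups],
        "v0": float(v0), "growth_rate": float(growth_rate),
        "days": [float(t) for t in days], "noise_cv": float(noise_cv),
        "aspect_ratio": float(aspect_ratio), "seed": int(seed)})
    return pd.DataFrame(rows), gt
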
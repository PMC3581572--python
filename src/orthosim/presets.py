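"""The benchmark scenario grid.

Six phylogeny parameter classes -- three bacteria-like (G1-G3, 30 species,
long trees) and three mammalia-like (M1-M3, 20 species, short trees) -- are
crossed with four scenario series:

* ``dup``      duplication/loss levels 10-40% duplication background;
* ``duploss``  unequal duplication vs loss rates;
* ``lgt``      lateral-transfer levels 0-80% transfer background;
* ``indel``    insertion/deletion rates 0.00025-0.002 per site per PAM;
* ``artefact`` ambiguity masking with mean length proportion 6-18%.

Every rate is per PAM unit (per gene for duplication/loss/LGT, per site for
indels).  The phylogeny classes carry the published summary statistics of
the original species trees; surrogate trees are generated to match them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .evolver import ScenarioConfig, gamma_params_from_mean_sd
from .phylo import SpeciesTree, TreeStats, surrogate_tree

__all__ = [
    "PhylogenyClass",
    "PHYLOGENY_CLASSES",
    "Preset",
    "scenario_grid",
    "list_presets",
    "get_preset",
    "build_config",
    "build_species_tree",
]


@dataclass(frozen=True)
class PhylogenyClass:
    """Target statistics of one species-tree regime (PAM units)."""

    name: str
    n_species: int
    stats: TreeStats
    length_mean: float  # root sequence length distribution (residues)
    length_sd: float


def _cls(name, n, total, min_h, max_h, mean_h, mean_pd, lmean, lsd):
    return PhylogenyClass(
        name=name,
        n_species=n,
        stats=TreeStats(
            n_leaves=n,
            total_length=total,
            min_height=min_h,
            max_height=max_h,
            mean_height=mean_h,
            mean_pairwise_distance=mean_pd,
        ),
        length_mean=lmean,
        length_sd=lsd,
    )


PHYLOGENY_CLASSES: dict[str, PhylogenyClass] = {
    c.name: c
    for c in [
        _cls("G1", 30, 763.6, 31.70, 77.80, 41.36, 72.60, 320.0, 190.0),
        _cls("G2", 30, 831.0, 41.80, 80.12, 55.70, 92.31, 320.0, 190.0),
        _cls("G3", 30, 945.6, 46.59, 124.6, 62.64, 90.07, 320.0, 190.0),
        _cls("M1", 20, 101.2, 14.70, 19.18, 17.48, 14.50, 480.0, 330.0),
        _cls("M2", 20, 119.9, 11.55, 23.85, 14.79, 16.80, 480.0, 330.0),
        _cls("M3", 20, 57.59, 7.693, 10.47, 8.996, 8.74, 480.0, 330.0),
    ]
}

_CLASS_ORDER = ["G1", "G2", "G3", "M1", "M2", "M3"]

# scenario series rates, one value per phylogeny class in _CLASS_ORDER
_DUP_LEVELS = {  # duplication background level -> duplication = loss rate
    10: [0.003, 0.002, 0.0017, 0.0065, 0.0065, 0.013],
    20: [0.006, 0.004, 0.0035, 0.013, 0.016, 0.025],
    30: [0.0105, 0.008, 0.007, 0.025, 0.03, 0.05],
    40: [0.017, 0.0125, 0.0115, 0.0455, 0.055, 0.09],
}

_DUPLOSS_SCENARIOS = {  # name -> (dup rates, loss rates)
    "dup10-loss3x": (
        [0.0026, 0.002, 0.0017, 0.0065, 0.007, 0.0122],
        [0.0078, 0.006, 0.0051, 0.0195, 0.021, 0.0366],
    ),
    "dup30-loss-third": (
        [0.0087, 0.0066, 0.00585, 0.0201, 0.0246, 0.0399],
        [0.0029, 0.0022, 0.00195, 0.0067, 0.0082, 0.0133],
    ),
    "dup40-loss0": (
        [0.0125, 0.0093, 0.0083, 0.03, 0.035, 0.0585],
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    ),
}

_LGT_BASE_DUPLOSS = [0.0025, 0.0018, 0.0017, 0.0058, 0.0068, 0.011]
_LGT_LEVELS = {  # transfer background level -> LGT rate
    0: None,  # falls back to the 10%-duplication baseline, no LGT
    10: [0.0025, 0.0018, 0.0017, 0.0058, 0.0068, 0.011],
    20: [0.0045, 0.0034, 0.0031, 0.0108, 0.0136, 0.022],
    40: [0.0085, 0.0064, 0.0059, 0.0215, 0.025, 0.0405],
    60: [0.0125, 0.0092, 0.0087, 0.032, 0.038, 0.063],
    80: [0.0175, 0.0128, 0.0127, 0.097, 0.064, 0.19],
}

_INDEL_DUPLOSS = [0.0025, 0.0018, 0.0017, 0.0065, 0.0065, 0.013]
_INDEL_LGT = [0.0025, 0.0018, 0.0017, 0.0, 0.0, 0.0]
_INDEL_RATES = [0.00025, 0.0005, 0.001, 0.002]

_ARTEFACT_LEVELS = [6, 9, 12, 15, 18]  # percent mean length proportion

BASELINE_INDEL_RATE = 0.000125
DEFAULT_REPLICATES = 5


@dataclass(frozen=True)
class Preset:
    """One named scenario cell: configuration plus its grid provenance."""

    name: str
    phylogeny: str
    series: str
    level: str
    provenance: str
    config: ScenarioConfig


def _base_config(cls: PhylogenyClass, n_families: int, seed: int) -> ScenarioConfig:
    shape, scale = gamma_params_from_mean_sd(cls.length_mean, cls.length_sd)
    return ScenarioConfig(
        n_root_families=n_families,
        length_shape=shape,
        length_scale=scale,
        min_length=50,
        ins_rate=BASELINE_INDEL_RATE,
        del_rate=BASELINE_INDEL_RATE,
        n_replicates=DEFAULT_REPLICATES,
        seed=seed,
    )


def scenario_grid(n_families: int = 1000, seed: int = 0) -> list[Preset]:
    """Enumerate the full preset grid over all six phylogeny classes."""
    presets: list[Preset] = []
    for ci, cname in enumerate(_CLASS_ORDER):
        cls = PHYLOGENY_CLASSES[cname]
        base = _base_config(cls, n_families, seed)

        presets.append(
            Preset(
                name=f"baseline-{cname}",
                phylogeny=cname,
                series="baseline",
                level="-",
                provenance="baseline parameters (no gene-level events)",
                config=base,
            )
        )
        for level, rates in _DUP_LEVELS.items():
            presets.append(
                Preset(
                    name=f"dup-{level}-{cname}",
                    phylogeny=cname,
                    series="dup",
                    level=f"{level}%",
                    provenance=f"duplication series, {level}% duplication, "
                    f"class {cname}",
                    config=replace(base, dup_rate=rates[ci], loss_rate=rates[ci]),
                )
            )
        for sname, (dup, loss) in _DUPLOSS_SCENARIOS.items():
            presets.append(
                Preset(
                    name=f"{sname}-{cname}",
                    phylogeny=cname,
                    series="duploss",
                    level=sname,
                    provenance=f"unequal loss-rate series, {sname}, class {cname}",
                    config=replace(base, dup_rate=dup[ci], loss_rate=loss[ci]),
                )
            )
        for level, lgt in _LGT_LEVELS.items():
            if lgt is None:
                cfg = replace(
                    base,
                    dup_rate=_DUP_LEVELS[10][ci],
                    loss_rate=_DUP_LEVELS[10][ci],
                )
            else:
                cfg = replace(
                    base,
                    dup_rate=_LGT_BASE_DUPLOSS[ci],
                    loss_rate=_LGT_BASE_DUPLOSS[ci],
                    lgt_rate=lgt[ci],
                )
            presets.append(
                Preset(
                    name=f"lgt-{level}-{cname}",
                    phylogeny=cname,
                    series="lgt",
                    level=f"{level}%",
                    provenance=f"LGT series, {level}% transfer, class {cname}",
                    config=cfg,
                )
            )
        for rate in _INDEL_RATES:
            presets.append(
                Preset(
                    name=f"indel-{rate:g}-{cname}",
                    phylogeny=cname,
                    series="indel",
                    level=f"{rate:g}",
                    provenance=f"indel series, rate {rate:g} per site per PAM, "
                    f"class {cname}",
                    config=replace(
                        base,
                        dup_rate=_INDEL_DUPLOSS[ci],
                        loss_rate=_INDEL_DUPLOSS[ci],
                        lgt_rate=_INDEL_LGT[ci],
                        ins_rate=rate,
                        del_rate=rate,
                    ),
                )
            )
        for pct in _ARTEFACT_LEVELS:
            mu = pct / 100.0
            presets.append(
                Preset(
                    name=f"artefact-{pct}-{cname}",
                    phylogeny=cname,
                    series="artefact",
                    level=f"{pct}%",
                    provenance=f"artefact series, mean masked proportion {pct}%, "
                    f"class {cname}",
                    config=replace(
                        base,
                        dup_rate=_DUP_LEVELS[10][ci],
                        loss_rate=_DUP_LEVELS[10][ci],
                        artefact_mu=mu,
                        artefact_sd=mu / 3.0,
                    ),
                )
            )
    return presets


def list_presets(n_families: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Tabulate the preset grid with rates and provenance."""
    rows = []
    for p in scenario_grid(n_families, seed):
        c = p.config
        rows.append(
            {
                "name": p.name,
                "phylogeny": p.phylogeny,
                "series": p.series,
                "level": p.level,
                "dup_rate": c.dup_rate,
                "loss_rate": c.loss_rate,
                "lgt_rate": c.lgt_rate,
                "indel_rate": c.ins_rate,
                "artefact_mu": c.artefact_mu,
                "provenance": p.provenance,
            }
        )
    return pd.DataFrame(rows)


def get_preset(name: str, n_families: int = 1000, seed: int = 0) -> Preset:
    for p in scenario_grid(n_families, seed):
        if p.name == name:
            return p
    raise KeyError(f"unknown preset {name!r}")


def build_config(
    name: str, n_families: int = 1000, seed: int = 0
) -> tuple[ScenarioConfig, PhylogenyClass]:
    p = get_preset(name, n_families, seed)
    return p.config, PHYLOGENY_CLASSES[p.phylogeny]


def build_species_tree(
    cls: PhylogenyClass,
    rng: np.random.Generator,
    match: str = "total_length",
) -> SpeciesTree:
    """Surrogate species tree for a phylogeny class."""
    tree, _ = surrogate_tree(cls.n_species, cls.stats, rng, match=match)
    return tree
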
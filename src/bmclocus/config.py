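"""Run configuration: thresholds, weights, pfam lists and the clustering plan.

Defaults reproduce the published analysis parameters: shell-domain e-value
1e-05, pfam e-value 0.01, 10 kb windows, negative-component weight k = 0.5,
top-level clustering at inflation 2 / score cut-off 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .classify import DEFAULT_BMC_ASSOCIATED_PFAMS, DEFAULT_NEARBY_RADIUS
from .cluster import DEFAULT_PLAN
from .loci import SHELL_EVALUE, WINDOW_BP
from .profiles import PFAM_EVALUE
from .scoring import ScoringParams


@dataclass
class RunConfig:
    shell_evalue: float = SHELL_EVALUE
    pfam_evalue: float = PFAM_EVALUE
    window: int = WINDOW_BP
    scoring: ScoringParams = field(default_factory=ScoringParams)
    score_cutoff: float = 3.0
    inflation: float = 2.0
    plan: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PLAN)
    )
    bmc_associated_pfams: frozenset[str] = DEFAULT_BMC_ASSOCIATED_PFAMS
    nearby_radius: int = DEFAULT_NEARBY_RADIUS
    confirmed_anchors: dict[str, str] = field(default_factory=dict)
    characterized_loci: list[str] = field(default_factory=list)
    reference_loci: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        config = cls()
        scoring_data = data.pop("scoring", {})
        if scoring_data:
            identifying = scoring_data.pop("identifying_pfams", None)
            params = ScoringParams(**scoring_data)
            if identifying is not None:
                params.identifying_pfams = dict(identifying)
            config.scoring = params
        plan = data.pop("plan", None)
        if plan is not None:
            config.plan = {
                str(name): (float(v["inflation"]), float(v["score_cutoff"]))
                for name, v in plan.items()
            }
        bmc_pfams = data.pop("bmc_associated_pfams", None)
        if bmc_pfams is not None:
            config.bmc_associated_pfams = frozenset(bmc_pfams)
        for key, value in data.items():
            if not hasattr(config, key):
                raise ValueError(f"unknown configuration key {key!r}")
            setattr(config, key, value)
        return config

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "shell_evalue": self.shell_evalue,
            "pfam_evalue": self.pfam_evalue,
            "window": self.window,
            "score_cutoff": self.score_cutoff,
            "inflation": self.inflation,
            "scoring": {
                "k": self.scoring.k,
                "identifying_pfams": dict(self.scoring.identifying_pfams),
                "identifying_boost": self.scoring.identifying_boost,
                "distance_weights": dict(self.scoring.distance_weights),
                "rare_floor": self.scoring.rare_floor,
                "combine_rule": self.scoring.combine_rule,
                "cooccurrence_subset_fraction": self.scoring.cooccurrence_subset_fraction,
            },
            "plan": {
                name: {"inflation": i, "score_cutoff": s}
                for name, (i, s) in self.plan.items()
            },
            "bmc_associated_pfams": sorted(self.bmc_associated_pfams),
            "nearby_radius": self.nearby_radius,
            "confirmed_anchors": dict(self.confirmed_anchors),
            "characterized_loci": list(self.characterized_loci),
            "reference_loci": list(self.reference_loci),
        }
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=False)
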
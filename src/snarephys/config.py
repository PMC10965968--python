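"""Run configuration: schema-validated stage parameters for pipelines."""

from __future__ import annotations

import hashlib
import json
from typing import List, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

from .polymer import DumbbellConfig, ThermalContext, WLCParams

__all__ = ["RunConfig", "DumbbellSection", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DnaSection(_Strict):
    persistence_nm: float = 50.0
    contour_nm: float = 770.0
    stretch_pN: Optional[float] = 1000.0


class PeptideSection(_Strict):
    persistence_nm: float = 0.6
    residue_nm: float = 0.365


class TrapSection(_Strict):
    inv_stiffness_nm_per_pN: float = 10.0


class DumbbellSection(_Strict):
    dna: DnaSection = Field(default_factory=DnaSection)
    peptide: PeptideSection = Field(default_factory=PeptideSection)
    trap: TrapSection = Field(default_factory=TrapSection)
    core_offset_nm: float = 2.0

    def build(self) -> DumbbellConfig:
        return DumbbellConfig(
            dna_handle=WLCParams(
                self.dna.persistence_nm, self.dna.contour_nm, self.dna.stretch_pN
            ),
            peptide_persistence=self.peptide.persistence_nm,
            residue_contour=self.peptide.residue_nm,
            trap_stiffness_sum_inverse=self.trap.inv_stiffness_nm_per_pN,
            core_offset=self.core_offset_nm,
        )


class HMMSection(_Strict):
    n_states: int = 2
    seed: int = 0
    em_max_samples: int = 1_200_000


class SucroseSection(_Strict):
    onset_s: float = 1.0
    duration_s: float = 7.0
    concentration_mM: int = 500


class RunConfig(_Strict):
    """Top-level pipeline configuration; unknown keys are rejected."""

    stages: List[Literal["simulate", "hmm", "landscape", "sucrose-fit", "train-metrics"]] = Field(
        default_factory=lambda: ["simulate", "hmm", "landscape"]
    )
    seed: int = 0
    temperature_K: float = 296.0
    output_dir: str = "results"
    log_level: str = "INFO"
    dumbbell: DumbbellSection = Field(default_factory=DumbbellSection)
    hmm: HMMSection = Field(default_factory=HMMSection)
    sucrose: SucroseSection = Field(default_factory=SucroseSection)
    inputs: List[str] = Field(default_factory=list)

    def thermal(self) -> ThermalContext:
        return ThermalContext(self.temperature_K)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    with open(path) as fh:
        doc = json.load(fh)
    return RunConfig.model_validate(doc)
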
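"""Runtime configuration: defaults, TOML loading and pretty-printing."""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path


@dataclass
class AlignConfig:
    pocket_epsilon: float = 1.0
    ligand_epsilon: float = 0.5
    n_seeds: int = 10
    min_clique: int = 3


@dataclass
class ConformerConfig:
    n: int = 20
    backend: str = "auto"


@dataclass
class SearchConfig:
    cutoff: float = 12.0
    top_k: int = 10


@dataclass
class ScoringConfig:
    scorer: str = "surrogate"
    command: str = ""


@dataclass
class EvalConfig:
    top_k: int = 1
    cutoffs: tuple[float, ...] = (1.0, 2.0, 5.0)


@dataclass
class FixtureSection:
    n_receptor_residues: int = 24
    ligand_size: int = 8
    pocket_noise_sigma: float = 0.3
    decoy_count: int = 9


@dataclass
class Config:
    align: AlignConfig = field(default_factory=AlignConfig)
    conformers: ConformerConfig = field(default_factory=ConformerConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    fixtures: FixtureSection = field(default_factory=FixtureSection)

    @classmethod
    def load(cls, path: str | Path | None) -> "Config":
        """Defaults, overridden section-by-section from a TOML file."""
        config = cls()
        if path is None:
            return config
        data = tomllib.loads(Path(path).read_text())
        for section_field in fields(cls):
            if section_field.name not in data:
                continue
            section = getattr(config, section_field.name)
            overrides = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in data[section_field.name].items()
                if k in {f.name for f in fields(section)}
            }
            setattr(config, section_field.name, replace(section, **overrides))
        return config

    def show(self) -> str:
        """TOML-style rendering of every setting."""
        lines = []
        for section_field in fields(self):
            lines.append(f"[{section_field.name}]")
            for key, value in asdict(getattr(self, section_field.name)).items():
                if isinstance(value, str):
                    rendered = f'"{value}"'
                elif isinstance(value, (tuple, list)):
                    rendered = "[" + ", ".join(str(v) for v in value) + "]"
                else:
                    rendered = str(value)
                lines.append(f"{key} = {rendered}")
            lines.append("")
        return "\n".join(lines)
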
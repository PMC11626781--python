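"""Run configuration: one human-readable YAML file, CLI flags override keys.

Every analysis run writes its fully resolved configuration next to its
outputs, so a run can be reproduced exactly from the output directory.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # inputs
    input_path: str | None = None
    input_format: str | None = None       # pdb / mmcif / auto
    chain_a: str = "A"
    chain_b: str = "B"
    c_chains: tuple[str, str] = ("A", "B")   # C-terminal donor dimer
    n_chains: tuple[str, str] = ("C", "D")   # N-terminal donor dimer
    # geometry parameters
    axis_window: int = 5
    c_window: tuple[int, int] = (150, 161)
    n_window: tuple[int, int] = (1, 12)
    distance_cutoff: float = 6.0
    # contacts / SASA
    contact_band: tuple[float, float] = (-0.4, 0.6)
    radii_table: str = "bondi"
    probe_radius: float = 1.4
    n_quadrature_points: int = 960
    # lattice
    lattice_max_distance: float | None = None
    # reproducibility
    seed: int = 0
    output_dir: str = "coilgeom_out"
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.axis_window < 3 or self.axis_window % 2 == 0:
            raise ValueError("axis_window must be odd and >= 3")
        if self.n_quadrature_points < 100:
            raise ValueError("n_quadrature_points must be >= 100")
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        if self.contact_band[0] >= self.contact_band[1]:
            raise ValueError("contact band must be (low, high)")
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra.update(extra)
        for name in ("c_chains", "n_chains", "c_window", "n_window", "contact_band"):
            val = getattr(cfg, name)
            if isinstance(val, list):
                setattr(cfg, name, tuple(val))
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = asdict(self)
        for k, v in data.items():
            if isinstance(v, tuple):
                data[k] = list(v)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path
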
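"""Run configuration: every threshold and mode switch of a prediction run.

Settings use the historical flat ``key = value`` names so a run's settings
file can be re-read verbatim as a config file.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

MODES = ("dna", "dc", "protein", "mut_dna", "mut_protein")
BACKENDS = ("builtin", "external")


@dataclass
class BadgeConfig:
    """Thresholds and switches for one prediction run.

    Identity/coverage cuts are percentages (inclusive ``>=``);
    ``min_occurrence`` is the fraction of target-group genomes a gene
    family must occur in. The dc screen (step 4) is the *more* sensitive
    one, so its cutoffs must not exceed the primary megablast-level cuts.
    """

    megablast_perc_identity_cut: float = 95.0
    query_cov_cut: float = 95.0
    subject_cov_cut: float = 95.0
    min_occurrence: float = 1.0
    enable_dc_filter: bool = True
    dc_perc_identity_cut: float = 80.0
    dc_query_cov_cut: float = 60.0
    enable_short_hit_filter: bool = True
    max_blastn_len_cut: int = 100
    mode: str = "dna"
    backend: str = "builtin"
    clean_up: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.min_occurrence <= 1:
            raise ValueError("min_occurrence must lie in (0, 1]")
        for name in (
            "megablast_perc_identity_cut", "query_cov_cut", "subject_cov_cut",
            "dc_perc_identity_cut", "dc_query_cov_cut",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if self.dc_perc_identity_cut > self.megablast_perc_identity_cut:
            raise ValueError(
                "dc_perc_identity_cut must not exceed megablast_perc_identity_cut "
                "(the dc screen is the more sensitive one)"
            )
        if self.dc_query_cov_cut > self.query_cov_cut:
            raise ValueError("dc_query_cov_cut must not exceed query_cov_cut")
        if self.max_blastn_len_cut < 0:
            raise ValueError("max_blastn_len_cut must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.backend not in BACKENDS:
            raise ValueError(f"backend must be one of {BACKENDS}")

    def to_file(self, path: str | Path) -> None:
        """Write every setting verbatim in flat ``key = value`` form."""
        lines = []
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "BadgeConfig":
        kwargs: dict = {}
        valid = {f.name: f.type for f in fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in valid:
                raise ValueError(f"{path}:{lineno}: unknown setting {key!r}")
            kwargs[key] = _coerce(key, val)
        return cls(**kwargs)


def _coerce(key: str, val: str):
    if key in ("enable_dc_filter", "enable_short_hit_filter", "clean_up"):
        if val.lower() in ("true", "1", "yes"):
            return True
        if val.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"setting {key}: expected boolean, got {val!r}")
    if key in ("mode", "backend"):
        return val
    if key == "max_blastn_len_cut":
        return int(val)
    return float(val)
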
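"""Pipeline configuration with the published defaults.

Every threshold used by the detection chain is a key here so a YAML file can
override it: the 50 lx daylight rule, the 20 s bout/gap pruning, the 5 min
efficiency window, the −6° civil-twilight night flag, the 0.2 / 2 Hz median
filter cut-offs, the 30 min edge trim, and the 65 g feathered-chick mass.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # accel preprocessing
    highpass_fc_hz: float = 0.2     # gravity-removal median filter cut-off
    lowpass_fc_hz: float = 2.0      # noise-smoothing median filter cut-off
    bin_s: float = 5.0              # aggregation bin width
    trim_s: float = 1800.0          # edge trim at both ends
    static_win_s: float = 10.0      # autocalibration static-window length
    static_sd_g: float = 0.013      # per-axis SD threshold for "static"
    autocalibrate: bool = True
    # hmm
    hmm_eps_g: float = 1e-4         # log(odba + eps)
    hmm_tol: float = 1e-6           # Baum–Welch loglik tolerance
    hmm_max_iter: int = 200
    # postprocess
    lx_thresh: float = 50.0         # daylight brooding must dip below this
    min_dark_bins: int = 1          # "at least for a part of the bout"
    short_s: float = 20.0           # bouts/gaps up to this long are pruned
    night_elev_deg: float = -6.0    # sun below this ⇒ night
    break_direction: str = "below"  # cooling onset ends a bout ("below"/"above")
    adjust_sustain_bins: int = 6    # onset must hold this many consecutive bins
    min_statebins: int = 10         # bins per state needed for temp-diff stats
    feathered_mass_g: float = 65.0  # light sensor covered by feathers
    # summaries
    efficiency_min_bout_s: float = 300.0  # bouts longer than 5 min
    efficiency_skip_s: float = 300.0      # first 5 min excluded
    round_minutes: bool = False     # integer binomial numerators at export

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
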
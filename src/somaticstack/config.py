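"""Pipeline configuration with the stack's default thresholds."""
from __future__ import annotations

import yaml

#: every tunable threshold of the post-calling stack
DEFAULTS = {
    "amp_threshold": 0.2,
    "del_threshold": -0.235,
    "sv_min_size": 500,
    "sv_slop": 300,
    "sv_reciprocal": 0.5,
    "pon_min_individuals": 2,
    "pon_sv_max_distance": 300,
    "germline_maf": 0.01,
    "tumor_vaf_min": 0.0001,
    "normal_vaf_max": 0.2,
    "min_depth": 2,
    "pileup_mq": 10,
    "pileup_bq": 10,
    "pileup_indel_maxlen": 10,  # exclusive: indels of this net length use caller counts
    "hc_min_split_reads": 3,
    "hc_changepoint_dist": 1000,
    "lancet_pad": 250,
    "mismatch_depth": 8,
}


class ConfigError(ValueError):
    pass


def load_config(path=None, overrides=None) -> dict:
    """Defaults, optionally overlaid with a YAML file and explicit overrides."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a mapping")
        cfg.update(data)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg
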
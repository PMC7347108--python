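"""Cascade configuration: every stochastic rate and distribution of the model.

Defaults are taken from the measured frequencies of the bridge cascade where
a measurement exists (bridge half-life ~10 h on a 24 h cycle, 27% of bridge
DNA replicated in interphase, 52%/65% micronucleation after broken/unbroken
bridges, 80% bridge-chromosome content and 62% centromere retention in
micronuclei, 8/9 vs 1/10 post-mitotic vs interphase micronuclear
chromothripsis, 85% acrocentric translocation partners, 183 bp median
templated-insertion size, 1-10 kb insertion-source hotspots, 5:2:6
blunt:microhomology:untemplated junction mix).  Where no measurement exists
the default is a stated modeling assumption (see docs/methods.md).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, fields, replace

import yaml


class ConfigError(ValueError):
    """Raised with a combined report of all invalid configuration fields."""


@dataclass(frozen=True)
class CascadeConfig:
    # fusion
    p_fusion_type: tuple[float, float, float] = (0.4, 0.4, 0.2)  # sister, nonsister, chromosome_type
    fusion_chrom: str = "chrA"  # bridge-prone target chromosome
    fusion_haplotype: str = "A"

    # bridge lifetime (exponential, right-censored at the next mitosis)
    bridge_lifetime_median_h: float = 10.0
    cell_cycle_h: float = 24.0

    # breakage
    p_fragmentation: float = 0.5  # local fragmentation vs simple break
    min_break_offset: int = 2_500_000  # bp between fusion point and break
    fragment_count_extra_mean: float = 3.0  # fragments = 1 + Poisson(mean)
    fragment_length_range: tuple[int, int] = (100_000, 5_000_000)  # log-uniform
    replicated_fraction: float = 0.27  # bridge DNA replicated in interphase
    retention_floor: float = 0.25  # p(retain fragment) = replicated_fraction + floor
    p_circularize_fragment: float = 0.0  # ecDNA option

    # TST jumps
    p_tst: float = 0.2  # per bridge breakage
    tst_insertion_median_bp: float = 183.0
    tst_insertion_sigma: float = 0.65  # log-normal sigma; ~95% mass in [50, 1000] bp
    tst_hotspot_window: int = 10_000
    tst_breakpoints_per_hotspot: float = 10.0  # Poisson mean
    tst_hotspots_range: tuple[int, int] = (2, 10)
    tst_hotspot_elsewhere_p: float = 0.15  # hotspot on an intact chromosome
    tst_chain_length_min: int = 4
    tst_chain_length_extra_mean: float = 6.0  # insertions = min + Poisson(mean)
    tst_homology_mix: tuple[float, float, float] = (5.0, 2.0, 6.0)  # blunt:mh:untemplated

    # kataegis
    p_kataegis: float = 0.5  # among TST-positive events
    kataegis_min_mutations: int = 6
    kataegis_extra_mutations_mean: float = 4.0
    kataegis_imd_mean_bp: float = 300.0

    # mitotic second wave
    p_mitotic_second_wave: float = 1.0
    second_wave_breaks_mean: float = 8.0  # Poisson, within the stub region
    stub_region_bp: int = 5_000_000  # under-replicated window behind the break

    # micronucleation
    p_micronucleus_broken: float = 0.52
    p_micronucleus_unbroken: float = 0.65
    p_mn_contains_bridge_chrom: float = 0.80
    p_mn_centromere: float = 0.62
    p_mn_centromere_inactivation: float = 1.0
    p_mn_chromothripsis_after_mitosis: float = 8.0 / 9.0
    p_interphase_chromothripsis_mn: float = 1.0 / 10.0

    # downstream BFB evolution
    p_acrocentric_partner: float = 0.85
    p_bfb_continue: float = 0.5  # per division, per uncapped end
    p_stabilize: float = 0.2  # per division: cap by translocation
    bfb_terminal_delta_range: tuple[int, int] = (500_000, 3_000_000)  # log-uniform bp

    # bookkeeping constants (recorded, unused by default)
    s_phase_entry_bridge_h: float = 8.3
    s_phase_entry_control_h: float = 7.3

    seed: int = 0

    # -- derived quantities -------------------------------------------------

    @property
    def bridge_lifetime_rate(self) -> float:
        """Exponential rate such that the median equals the configured half-life."""
        return math.log(2.0) / self.bridge_lifetime_median_h

    @property
    def p_break_before_mitosis(self) -> float:
        """P(lifetime < cycle) = 1 - 2^(-cycle/median)."""
        return 1.0 - 2.0 ** (-self.cell_cycle_h / self.bridge_lifetime_median_h)

    @property
    def p_fragment_retained(self) -> float:
        return self.replicated_fraction + self.retention_floor

    # -- validation ---------------------------------------------------------

    def validate(self) -> "CascadeConfig":
        """Return self; raise ConfigError listing every invalid field."""
        errs: list[str] = []

        def prob(name: str, v: float) -> None:
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name}={v!r} not in [0, 1]")

        for name in (
            "p_fragmentation", "p_circularize_fragment", "p_tst", "p_kataegis",
            "p_mitotic_second_wave", "p_micronucleus_broken", "p_micronucleus_unbroken",
            "p_mn_contains_bridge_chrom", "p_mn_centromere",
            "p_mn_centromere_inactivation", "p_mn_chromothripsis_after_mitosis",
            "p_interphase_chromothripsis_mn", "p_acrocentric_partner",
            "p_bfb_continue", "p_stabilize", "replicated_fraction", "retention_floor",
            "tst_hotspot_elsewhere_p",
        ):
            prob(name, getattr(self, name))
        if abs(sum(self.p_fusion_type) - 1.0) > 1e-9 or min(self.p_fusion_type) < 0:
            errs.append(f"p_fusion_type={self.p_fusion_type} must be a probability vector")
        if self.p_fragment_retained > 1.0:
            errs.append("replicated_fraction + retention_floor exceeds 1")
        for name in (
            "bridge_lifetime_median_h", "cell_cycle_h", "fragment_count_extra_mean",
            "tst_insertion_median_bp", "tst_insertion_sigma",
            "tst_breakpoints_per_hotspot", "tst_chain_length_extra_mean",
            "kataegis_imd_mean_bp", "second_wave_breaks_mean",
            "kataegis_extra_mutations_mean",
        ):
            v = getattr(self, name)
            if not v >= 0 or (name.endswith("_h") or "median" in name or "sigma" in name) and v <= 0:
                errs.append(f"{name}={v!r} must be positive")
        for name in ("fragment_length_range", "tst_hotspots_range", "bfb_terminal_delta_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                errs.append(f"{name}=({lo},{hi}) must satisfy 0 < lo <= hi")
        if self.min_break_offset < 0:
            errs.append("min_break_offset must be >= 0")
        if self.kataegis_min_mutations < 1:
            errs.append("kataegis_min_mutations must be >= 1")
        if errs:
            raise ConfigError("invalid configuration:\n  " + "\n  ".join(errs))
        return self

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        clean = {}
        for f in fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            clean[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**clean).validate()

    @classmethod
    def load(cls, path) -> "CascadeConfig":
        """Read a YAML or JSON config file (YAML is a JSON superset here)."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def dump(self, path) -> None:
        text = yaml.safe_dump(
            json.loads(json.dumps(self.to_dict())), sort_keys=False
        )
        with open(path, "w") as fh:
            fh.write(text)

    def with_(self, **kw) -> "CascadeConfig":
        return replace(self, **kw).validate()
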
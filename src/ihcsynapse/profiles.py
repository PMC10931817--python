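"""Generator profiles: the study conditions for synthetic cochlear stacks.

A :class:`GeneratorProfile` bundles everything the synthetic-stack generator
needs to emulate one age group at one tonotopic location: per-side expected
synapse counts, animal-level count dispersion, right-skewed volume laws for
pre- and postsynaptic elements, optical parameters (voxel spacing, PSF,
noise) and the rate of broad-spectrum lipofuscin-like distractors.

The packaged profiles (``PROFILES``) encode the young-adult and quiet-aged
Mongolian gerbil groups at the three analysed locations (1, 2 and 16 kHz,
i.e. 2.51, 3.8 and 8.13 mm from the cochlear apex).  The 16 kHz per-side
means are the published group means (young: 13.7 modiolar / 8.3 pillar;
aged: 7.7 / 9.4); the 1 and 2 kHz totals are chosen so the three-location
grand means equal the published 21.6 (young) and 17.2 (aged) synapses per
IHC, with an even side split at the apical locations where no side effect
was reported.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Tuple

import yaml

__all__ = ["GeneratorProfile", "PROFILES", "FREQUENCY_PLACE_MM", "get_profile"]

#: Tonotopic location labels and their distance from the cochlear apex (mm).
#: Configuration constants of the study design, not computed from a map.
FREQUENCY_PLACE_MM = {"1kHz": 2.51, "2kHz": 3.8, "16kHz": 8.13}


@dataclass
class GeneratorProfile:
    """Study conditions for one age group at one cochlear location.

    Volumes are in µm³, lengths in µm.  Axis-ordered tuples follow the
    array convention (z, y, x) where z is the optical/modiolar–pillar
    axis, y the hair-cell top→bottom axis and x the apex→base row axis.
    """

    name: str = "custom"
    location_label: str = "16kHz"
    age_group: str = "young_adult"

    # per-IHC expected pair counts and animal-level dispersion
    expected_count_modiolar: float = 13.7
    expected_count_pillar: float = 8.3
    #: log-sd of the multiplicative per-animal lognormal frailty on counts
    count_noise: float = 0.12

    # right-skewed (lognormal) volume laws, per side and channel
    pre_volume_median_modiolar: float = 0.16
    pre_volume_median_pillar: float = 0.11
    post_volume_median_modiolar: float = 0.30
    post_volume_median_pillar: float = 0.21
    volume_log_sigma: float = 0.5
    #: floor on planted volumes; puncta below this are not reliably
    #: imaged at the packaged optics, so the law is truncated here
    min_volume_um3: float = 0.03
    #: target Spearman correlation between pre and post volumes of a pair
    pre_post_volume_correlation: float = 0.6

    # optics / rendering; the PSF width reflects post-deconvolution
    # quality (the stacks emulate deconvolved confocal data)
    psf_sigma_um: Tuple[float, float, float] = (0.13, 0.05, 0.05)
    spacing_um: Tuple[float, float, float] = (0.3, 0.08, 0.08)
    peak_intensity: float = 250.0
    background_level: float = 2.0
    #: 1.0 = pure Poisson photon statistics; 0 disables noise entirely
    photon_noise_scale: float = 1.0
    haircell_intensity: float = 40.0

    # lipofuscin-like broad-spectrum distractors (aged tissue)
    lipofuscin_rate: float = 0.0
    lipofuscin_volume_median: float = 5.0
    lipofuscin_log_sigma: float = 0.35
    lipofuscin_volume_floor: float = 2.0

    # cell-row geometry
    cell_semi_axes_um: Tuple[float, float, float] = (3.5, 12.0, 3.6)
    cell_pitch_um: float = 8.4
    margin_um: Tuple[float, float, float] = (1.5, 2.0, 2.0)
    #: hard-core minimum distance between synapse centres of one cell
    min_separation_um: float = 1.2
    #: basolateral band for synapse placement, as top→bottom fractions
    basolateral_band: Tuple[float, float] = (0.68, 0.93)
    #: modiolar–pillar placement band on the modiolar half (mirrored on
    #: the pillar half); margins keep planted sides unambiguous
    side_band: Tuple[float, float] = (0.08, 0.44)

    seed: int = 0

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        if self.expected_count_modiolar < 0 or self.expected_count_pillar < 0:
            raise ValueError("expected per-side counts must be nonnegative")
        if any(s <= 0 for s in self.psf_sigma_um):
            raise ValueError("psf_sigma_um must be strictly positive")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing_um must be strictly positive")
        if self.count_noise < 0:
            raise ValueError("count_noise must be nonnegative")
        if self.pre_volume_median_modiolar < self.pre_volume_median_pillar:
            raise ValueError(
                "modiolar pre-volume median must be >= pillar median "
                "when a volume gradient is requested"
            )
        if self.post_volume_median_modiolar < self.post_volume_median_pillar:
            raise ValueError(
                "modiolar post-volume median must be >= pillar median "
                "when a volume gradient is requested"
            )
        if not 0.0 <= self.pre_post_volume_correlation <= 1.0:
            raise ValueError("pre_post_volume_correlation must be in [0, 1]")
        lo, hi = self.basolateral_band
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("basolateral_band must be an increasing pair in [0, 1]")
        lo, hi = self.side_band
        if not 0.0 <= lo < hi <= 0.5:
            raise ValueError("side_band must be an increasing pair in [0, 0.5]")

    def __post_init__(self) -> None:
        # YAML loads tuples as lists; normalise so round-trips compare equal
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, list):
                object.__setattr__(self, f.name, tuple(v))
        self.validate()

    @property
    def distance_from_apex_mm(self) -> float:
        return FREQUENCY_PLACE_MM.get(self.location_label, float("nan"))

    @property
    def expected_count_total(self) -> float:
        return self.expected_count_modiolar + self.expected_count_pillar

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorProfile":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorProfile":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "GeneratorProfile":
        return dataclasses.replace(self, **kw)


def _young(label: str, mod: float, pil: float) -> GeneratorProfile:
    return GeneratorProfile(
        name=f"gerbil_{label.replace('kHz', 'k')}_young",
        location_label=label,
        age_group="young_adult",
        expected_count_modiolar=mod,
        expected_count_pillar=pil,
        lipofuscin_rate=0.0,
    )


def _aged(label: str, mod: float, pil: float) -> GeneratorProfile:
    return GeneratorProfile(
        name=f"gerbil_{label.replace('kHz', 'k')}_aged",
        location_label=label,
        age_group="quiet_aged",
        expected_count_modiolar=mod,
        expected_count_pillar=pil,
        lipofuscin_rate=0.5,
        # quiet-aged gradients keep the modiolar>pillar direction; the
        # postsynaptic gradient sharpens slightly with age
        post_volume_median_modiolar=0.32,
        post_volume_median_pillar=0.20,
    )


#: Packaged study profiles: age group x tonotopic location.
PROFILES = {
    p.name: p
    for p in [
        _young("1kHz", 11.3, 11.3),   # total 22.6
        _young("2kHz", 10.1, 10.1),   # total 20.2
        _young("16kHz", 13.7, 8.3),   # total 22.0; grand mean 21.6
        _aged("1kHz", 9.85, 9.85),    # total 19.7
        _aged("2kHz", 7.4, 7.4),      # total 14.8
        _aged("16kHz", 7.7, 9.4),     # total 17.1; grand mean 17.2
    ]
}


def get_profile(name: str) -> GeneratorProfile:
    """Look up a packaged profile by name (e.g. ``gerbil_16k_young``)."""
    try:
        return PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; available: {sorted(PROFILES)}"
        ) from None
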
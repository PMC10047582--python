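"""Feature-table manifest: the deterministic column catalogue of an extraction.

Each column name is ``modality|filter|family|feature``.  The manifest length
is a function of the configuration (modalities x filter bank x families) and
is emitted explicitly rather than hard-coded, so any configuration's count is
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..phantom import MODALITIES
from .firstorder import FIRST_ORDER_NAMES
from .texture import FAMILY_FEATURE_NAMES

FAMILY_SIZES = {
    "firstorder": len(FIRST_ORDER_NAMES),          # 19
    **{fam: len(names) for fam, names in FAMILY_FEATURE_NAMES.items()},
}  # glcm 24, glrlm 16, glszm 16, ngtdm 5, gldm 14 -> 75 textural

ALL_FAMILIES = ("firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")


@dataclass
class FeatureConfig:
    """Extraction configuration: kernel, filter bank, families, binning."""

    kernel_radius_vox: int = 2
    filters: tuple[str, ...] = ("original",)
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0)
    wavelet: str = "haar"
    families: tuple[str, ...] = ("firstorder",)
    n_bins: int = 16
    modalities: tuple[str, ...] = MODALITIES

    def __post_init__(self) -> None:
        unknown = set(self.families) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        if self.kernel_radius_vox < 0:
            raise ValueError("kernel radius must be >= 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    def filter_ids(self) -> list[str]:
        ids: list[str] = []
        for f in self.filters:
            if f == "original":
                ids.append("original")
            elif f == "log":
                ids.extend(f"log@{s:g}mm" for s in self.log_sigmas_mm)
            elif f == "wavelet":
                ids.extend(f"wavelet@{b}" for b in
                           ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"))
            elif f == "lbp3d":
                ids.append("lbp3d")
            else:
                raise ValueError(f"unknown filter {f!r}")
        return ids


def family_feature_names(family: str) -> tuple[str, ...]:
    if family == "firstorder":
        return FIRST_ORDER_NAMES
    return FAMILY_FEATURE_NAMES[family]


def build_manifest(config: FeatureConfig) -> list[str]:
    """Ordered, unique column names for a configuration."""
    names = [
        f"{mod}|{fid}|{fam}|{feat}"
        for mod in config.modalities
        for fid in config.filter_ids()
        for fam in config.families
        for feat in family_feature_names(fam)
    ]
    if len(set(names)) != len(names):
        raise ValueError("manifest contains duplicate feature names")
    return names
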
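"""Voxel-grid containers for tau-PET volumes, the region atlas, and domain maps.

All volumes in a cohort must live on one shared grid (identical dimensions
and affine); there is no resampling in this package — spatial normalization
is assumed to have happened upstream. Volumes are read and written as
NIfTI-1 through nibabel, with the atlas label semantics carried in a JSON
side-car dictionary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

DOMAINS = ("MEM", "LAN", "EF", "VS")
ROI_NAMES = DOMAINS + ("GLOBAL", "TEMPORAL")

#: affine tolerance when deciding two volumes share a grid
AFFINE_ATOL = 1e-6


class GridMismatchError(ValueError):
    """Volumes that should share a grid do not."""


class SizingError(ValueError):
    """Grid too small to host all required region classes."""


@dataclass(frozen=True)
class LabelInfo:
    """Semantics of one atlas label."""

    name: str
    cortical_gm: bool = False
    off_target: bool = False
    braak_stage: int = 0  # 0 = not a Braak-stage region


@dataclass
class RegionAtlas:
    """Integer-labelled parcellation on the shared grid."""

    labels: np.ndarray  # int array, 3-D
    label_dict: dict[int, LabelInfo]
    affine: np.ndarray = field(default_factory=lambda: np.diag([2.0, 2.0, 2.0, 1.0]))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def _mask_where(self, pred) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        for lab, info in self.label_dict.items():
            if pred(info):
                mask |= self.labels == lab
        return mask

    def cortical_gm_mask(self) -> np.ndarray:
        return self._mask_where(lambda i: i.cortical_gm)

    def off_target_mask(self) -> np.ndarray:
        return self._mask_where(lambda i: i.off_target)

    def braak_mask(self, stages) -> np.ndarray:
        stages = set(stages)
        return self._mask_where(lambda i: i.braak_stage in stages)

    def brain_mask(self) -> np.ndarray:
        """All non-background voxels."""
        background = [lab for lab, i in self.label_dict.items() if i.name == "background"]
        mask = np.ones(self.shape, dtype=bool)
        for lab in background:
            mask &= self.labels != lab
        return mask


@dataclass
class DomainMap:
    """Binary meta-analytic activation mask for one cognitive domain."""

    domain: str
    mask: np.ndarray  # bool, 3-D
    affine: np.ndarray = field(default_factory=lambda: np.diag([2.0, 2.0, 2.0, 1.0]))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape


@dataclass
class TauVolume:
    """One subject's SUVR (or TPP) volume."""

    subject_id: str
    values: np.ndarray  # float, 3-D
    affine: np.ndarray = field(default_factory=lambda: np.diag([2.0, 2.0, 2.0, 1.0]))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def check_same_grid(*objs) -> None:
    """Raise GridMismatchError unless all objects share shape and affine."""
    ref = objs[0]
    for other in objs[1:]:
        if tuple(other.shape) != tuple(ref.shape):
            raise GridMismatchError(
                f"grid shape mismatch: {tuple(other.shape)} vs {tuple(ref.shape)}"
            )
        if not np.allclose(other.affine, ref.affine, atol=AFFINE_ATOL):
            raise GridMismatchError("affine mismatch beyond tolerance")


# ---------------------------------------------------------------------------
# NIfTI-1 / JSON round-tripping


def save_volume(vol: TauVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), vol.affine)
    nib.save(img, str(path))


def load_volume(path: str | Path, subject_id: str | None = None) -> TauVolume:
    img = nib.load(str(path))
    sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
    return TauVolume(sid, np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine))


def save_atlas(atlas: RegionAtlas, nii_path: str | Path, json_path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(atlas.labels, dtype=np.int16), atlas.affine)
    nib.save(img, str(nii_path))
    payload = {
        str(lab): {
            "name": info.name,
            "cortical_gm": info.cortical_gm,
            "off_target": info.off_target,
            "braak_stage": info.braak_stage,
        }
        for lab, info in atlas.label_dict.items()
    }
    Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_atlas(nii_path: str | Path, json_path: str | Path) -> RegionAtlas:
    img = nib.load(str(nii_path))
    raw = json.loads(Path(json_path).read_text())
    label_dict = {
        int(lab): LabelInfo(
            name=d["name"],
            cortical_gm=bool(d["cortical_gm"]),
            off_target=bool(d["off_target"]),
            braak_stage=int(d["braak_stage"]),
        )
        for lab, d in raw.items()
    }
    labels = np.asarray(img.get_fdata(), dtype=int)
    return RegionAtlas(labels, label_dict, np.asarray(img.affine))


def save_domain_map(dmap: DomainMap, path: str | Path) -> None:
    img = nib.Nifti1Image(dmap.mask.astype(np.uint8), dmap.affine)
    nib.save(img, str(path))


def load_domain_map(path: str | Path, domain: str) -> DomainMap:
    img = nib.load(str(path))
    return DomainMap(domain, np.asarray(img.get_fdata()) > 0.5, np.asarray(img.affine))
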
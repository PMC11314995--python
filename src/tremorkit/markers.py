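"""Extremity vocabulary and the default marker-to-extremity map.

The clinic annotates tremor per body extremity, using a closed set of 16
extremity names. Optical markers are grouped onto those extremities before
any spectral analysis. The exact 60-marker montage used clinically is not
published beyond a few named hand markers, so the default map below is an
illustrative full-body montage (60 markers, 16 extremities) consistent with
the named examples (R.Wrist, R.Thumb.M3, R.Finger3.M3 on the right hand).
Users with a different montage supply their own map as YAML/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from ._errors import ConfigError

#: Closed vocabulary of the 16 annotated body extremities.
EXTREMITIES: tuple[str, ...] = (
    "Head",
    "Shoulders",
    "Thorax",
    "Pelvis",
    "L_Dist_Arm",
    "R_Dist_Arm",
    "L_Hand",
    "R_Hand",
    "L_Prox_Arm",
    "R_Prox_Arm",
    "L_Dist_Leg",
    "R_Dist_Leg",
    "L_Foot",
    "R_Foot",
    "L_Prox_Leg",
    "R_Prox_Leg",
)


def _bilateral(extremity_suffix: str, names: list[str]) -> dict[str, str]:
    out = {}
    for side in ("L", "R"):
        for n in names:
            out[f"{side}.{n}"] = f"{side}_{extremity_suffix}"
    return out


#: Default illustrative 60-marker montage.
DEFAULT_MARKER_MAP: dict[str, str] = {
    # head (5)
    "Top.Head": "Head",
    "Front.Head": "Head",
    "Rear.Head": "Head",
    "L.Head": "Head",
    "R.Head": "Head",
    # shoulders (4)
    "L.Shoulder": "Shoulders",
    "R.Shoulder": "Shoulders",
    "L.Clavicle": "Shoulders",
    "R.Clavicle": "Shoulders",
    # thorax (6)
    "C7": "Thorax",
    "T10": "Thorax",
    "Sternum": "Thorax",
    "Xiphoid": "Thorax",
    "L.Scapula": "Thorax",
    "R.Scapula": "Thorax",
    # pelvis (5)
    "L.ASIS": "Pelvis",
    "R.ASIS": "Pelvis",
    "L.PSIS": "Pelvis",
    "R.PSIS": "Pelvis",
    "Sacrum": "Pelvis",
    # arms (3 + 3 + 3 per side)
    **_bilateral("Prox_Arm", ["Bicep", "Elbow", "Elbow.Med"]),
    **_bilateral("Dist_Arm", ["Forearm", "Wrist.Med", "Wrist.Lat"]),
    **_bilateral("Hand", ["Wrist", "Thumb.M3", "Finger3.M3"]),
    # legs (4 + 4 + 3 per side)
    **_bilateral("Prox_Leg", ["Thigh", "Thigh.Front", "Knee", "Knee.Med"]),
    **_bilateral("Dist_Leg", ["Shank", "Shank.Front", "Ankle", "Ankle.Med"]),
    **_bilateral("Foot", ["Heel", "Toe", "MT5"]),
}


def validate_marker_map(marker_map: dict[str, str]) -> dict[str, str]:
    """Check that every mapped extremity is in the closed vocabulary."""
    bad = sorted({e for e in marker_map.values() if e not in EXTREMITIES})
    if bad:
        raise ConfigError(
            f"unknown extremity names in marker map: {bad}; "
            f"valid names are {list(EXTREMITIES)}"
        )
    return marker_map


def load_marker_map(path: str | Path) -> dict[str, str]:
    """Load a marker->extremity map from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"marker map file {path} must contain a mapping")
    return validate_marker_map({str(k): str(v) for k, v in raw.items()})


def save_marker_map(marker_map: dict[str, str], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(marker_map, indent=1))
    else:
        path.write_text(yaml.safe_dump(marker_map, sort_keys=False))
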
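"""The a-priori cortical parcellation used throughout the pipeline.

Fifteen bilateral Desikan–Killiany regions: twelve temporal/parietal/occipital
regions expected to be affected in young-onset Alzheimer's disease, plus three
somatosensory regions (pre-, post- and paracentral) that are typically spared
until late disease and serve as control regions.
"""

from __future__ import annotations

import json
from pathlib import Path

#: ROI integer label -> (Desikan–Killiany name, affected-in-disease flag)
ROI_TABLE: dict[int, tuple[str, bool]] = {
    0: ("entorhinal", True),
    1: ("superiortemporal", True),
    2: ("fusiform", True),
    3: ("lateraloccipital", True),
    4: ("middletemporal", True),
    5: ("posteriorcingulate", True),
    6: ("inferiorparietal", True),
    7: ("parahippocampal", True),
    8: ("cuneus", True),
    9: ("inferiortemporal", True),
    10: ("precuneus", True),
    11: ("superiorparietal", True),
    12: ("precentral", False),
    13: ("postcentral", False),
    14: ("paracentral", False),
}

N_ROIS = len(ROI_TABLE)

METRICS = ("FA", "MD", "NDI", "ODI", "TF")

#: depth offsets in mm along the outward surface normal, outermost first:
#: +1 mm = cortical GM, 0 = GM/WM boundary, -1 mm = superficial WM,
#: -2 mm = superficial/deep WM mixture.
DEPTH_OFFSETS_MM = (1.0, 0.0, -1.0, -2.0)

DEPTH_LABELS = ("GM", "GMWM", "SWM", "SWMDWM")


def roi_name(label: int) -> str:
    try:
        return ROI_TABLE[label][0]
    except KeyError:
        raise KeyError(f"unknown ROI label {label!r}") from None


def roi_is_affected(label: int) -> bool:
    return ROI_TABLE[label][1]


def atlas_dict(roi_count: int = N_ROIS) -> dict:
    """JSON-serializable atlas: label -> name and affected/control flag.

    For synthetic cohorts with fewer than 15 ROIs the first ``roi_count``
    entries are used; more than 15 get generic names.
    """
    out = {}
    for lab in range(roi_count):
        if lab in ROI_TABLE:
            name, affected = ROI_TABLE[lab]
        else:
            name, affected = f"synthetic_roi_{lab}", True
        out[str(lab)] = {"name": name, "affected": bool(affected)}
    return out


def write_atlas_json(path: str | Path, roi_count: int = N_ROIS) -> Path:
    path = Path(path)
    path.write_text(json.dumps(atlas_dict(roi_count), indent=2) + "\n")
    return path
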
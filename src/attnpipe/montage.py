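"""Channel montage and color palette constants.

The montage is a 64-channel 10-20 layout (actiCHamp-style) that includes the
linked-mastoid reference channels TP9/TP10 and the 17-electrode posterior
cluster used for all ERP, alpha-power, and decoding analyses.
"""

from __future__ import annotations

#: 64-channel 10-20 montage (order is the canonical channel order everywhere).
CHANNELS_64 = [
    "Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
    "AFz", "F9", "F10",
]

#: The posterior cluster: Pz, P1/2, P3/4, P5/6, P7/8, POz, PO3/4, PO7/8, Oz, O1/2.
POSTERIOR_17 = [
    "Pz", "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8",
    "POz", "PO3", "PO4", "PO7", "PO8",
    "Oz", "O1", "O2",
]

#: Reference channels approximating the mastoids.
REFERENCE_PAIR = ("TP9", "TP10")

#: The seven-color stimulus palette.
PALETTE = ["red", "green", "blue", "yellow", "pink", "orange", "cyan"]

#: Frontal channels used for front/back weight-ratio checks.
FRONTAL = [ch for ch in CHANNELS_64 if ch[0] in "FA" and ch not in POSTERIOR_17]

assert len(CHANNELS_64) == 64
assert len(set(CHANNELS_64)) == 64
assert set(POSTERIOR_17) <= set(CHANNELS_64)


def channel_indices(names: list[str], montage: list[str] | None = None) -> list[int]:
    """Indices of ``names`` within ``montage`` (default: the 64-channel layout).

    Raises ``KeyError`` listing every missing name.
    """
    montage = CHANNELS_64 if montage is None else montage
    lookup = {ch: i for i, ch in enumerate(montage)}
    missing = [ch for ch in names if ch not in lookup]
    if missing:
        raise KeyError(f"channels missing from montage: {missing}")
    return [lookup[ch] for ch in names]
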
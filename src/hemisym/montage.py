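"""32-channel 10-20 montage bookkeeping for hemispheric network analysis.

The channel list follows the DEAP recording order (Geneva layout).  For
hemispheric networks each side contributes its 14 lateral electrodes plus
the 4 midline electrodes, giving two 18-node graphs; interhemispheric
lateral connections are discarded.  Lateral electrodes come in 14
homologous (mirror-symmetric) left/right pairs used for the nodal
asymmetry statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import MontageError

#: Channel order of the DEAP recordings (Geneva layout).
DEAP_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: Left lateral electrodes, ordered so that index i is the homolog of
#: RIGHT_LATERAL[i].
LEFT_LATERAL: tuple[str, ...] = (
    "Fp1", "AF3", "F7", "F3", "FC5", "FC1", "T7", "C3",
    "CP5", "CP1", "P7", "P3", "PO3", "O1",
)

RIGHT_LATERAL: tuple[str, ...] = (
    "Fp2", "AF4", "F8", "F4", "FC6", "FC2", "T8", "C4",
    "CP6", "CP2", "P8", "P4", "PO4", "O2",
)

MIDLINE: tuple[str, ...] = ("Fz", "Cz", "Pz", "Oz")


@dataclass(frozen=True)
class Montage:
    """Fixed electrode layout with hemisphere labels.

    Invariants: 14 left-lateral + 14 right-lateral + 4 midline = 32
    channels, and every lateral electrode has exactly one homolog at the
    same position in the opposite list.
    """

    channels: tuple[str, ...] = DEAP_CHANNELS
    left_lateral: tuple[str, ...] = LEFT_LATERAL
    right_lateral: tuple[str, ...] = RIGHT_LATERAL
    midline: tuple[str, ...] = MIDLINE

    def __post_init__(self) -> None:
        if len(self.left_lateral) != len(self.right_lateral):
            raise MontageError("lateral electrode lists must pair off 1:1")
        n = len(self.left_lateral) * 2 + len(self.midline)
        if n != len(self.channels):
            raise MontageError(
                f"montage has {len(self.channels)} channels but hemisphere "
                f"labels cover {n}"
            )
        labelled = set(self.left_lateral) | set(self.right_lateral) | set(self.midline)
        missing = set(self.channels) - labelled
        extra = labelled - set(self.channels)
        if missing or extra:
            raise MontageError(
                f"hemisphere labels do not partition the montage; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def homologous_pairs(self) -> tuple[tuple[str, str], ...]:
        """The 14 mirror-symmetric (left, right) electrode pairs."""
        return tuple(zip(self.left_lateral, self.right_lateral))

    def hemisphere_channels(self, side: str) -> tuple[str, ...]:
        """Node list for one hemispheric network: lateral + midline.

        Node i of the left network is the homolog of node i of the right
        network (midline nodes are shared and appear at the same indices).
        """
        if side == "left":
            return self.left_lateral + self.midline
        if side == "right":
            return self.right_lateral + self.midline
        raise MontageError(f"unknown hemisphere {side!r}; expected 'left' or 'right'")

    def index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise MontageError(f"channel {name!r} not in montage") from None

    def indices(self, names) -> list[int]:
        return [self.index(n) for n in names]

    def resolve(self, names) -> list[int]:
        """Map an external channel-name list onto montage order.

        Returns, for each montage channel, its position in ``names``.
        Raises :class:`MontageError` naming any montage channel absent
        from ``names``.
        """
        lookup = {str(n).strip(): i for i, n in enumerate(names)}
        missing = [c for c in self.channels if c not in lookup]
        if missing:
            raise MontageError(f"input is missing montage channels: {missing}")
        return [lookup[c] for c in self.channels]


def deap_montage() -> Montage:
    """The standard 32-channel DEAP montage."""
    return Montage()
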
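"""DBS lead trajectory reconstruction and contact placement.

A quadripolar DBS lead observed on postoperative CT is summarized by two
points: the tip T (most distal visible point of the electrode artifact)
and a shaft point S taken 20-30 mm dorsal to it.  The unit vector
u = (S - T)/|S - T| is the lead direction, and every point on the lead is
P = T + k*u for k >= 0.  Because the electrode geometry is known and
fixed, the four contact centers — and from the programmed stimulation
configuration the active-contact point — follow from the same line.

The default geometry is the Medtronic 3389: contacts 1.5 mm long,
0.5 mm apart, 1.27 mm diameter, numbered 0 (most distal) to 3.  Pulse
generators address the two leads of a bilateral implant in channel
blocks of four (0-3, 4-7, 8-11, 12-15), so a contact label is reduced
modulo 4 to its within-lead index.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InvalidObservationError",
    "InvalidConfigError",
    "LeadObservation",
    "LeadGeometry",
    "MODEL_3389",
    "ContactSet",
    "lead_direction",
    "contact_centers",
    "parse_active_config",
    "active_contact_point",
    "read_leads",
]


class InvalidObservationError(ValueError):
    """Tip and shaft points do not define a lead direction."""


class InvalidConfigError(ValueError):
    """A stimulation configuration label cannot be mapped to contacts."""


@dataclass(frozen=True)
class LeadObservation:
    """Tip + shaft point defining one implanted lead.

    ``tip`` is the most distal point of the lead artifact; ``shaft`` is a
    second point dorsal along the lead, typically 20-30 mm above the tip.
    """

    tip: np.ndarray
    shaft: np.ndarray
    hemisphere: Literal["left", "right"] = "right"
    patient_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "tip", np.asarray(self.tip, dtype=float))
        object.__setattr__(self, "shaft", np.asarray(self.shaft, dtype=float))
        if self.tip.shape != (3,) or self.shaft.shape != (3,):
            raise InvalidObservationError("tip and shaft must be 3D points")


@dataclass(frozen=True)
class LeadGeometry:
    """Fixed electrode geometry (lengths in mm)."""

    contact_length: float = 1.5
    contact_gap: float = 0.5
    diameter: float = 1.27
    tip_to_first_contact: float = 1.5
    n_contacts: int = 4

    def __post_init__(self) -> None:
        for name in ("contact_length", "contact_gap", "diameter", "tip_to_first_contact"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_contacts < 1:
            raise ValueError("n_contacts must be >= 1")

    @property
    def pitch(self) -> float:
        """Center-to-center spacing of adjacent contacts."""
        return self.contact_length + self.contact_gap

    def contact_center_offset(self, i: int) -> float:
        """Distance from the tip to the center of contact ``i``."""
        return self.tip_to_first_contact + self.contact_length / 2.0 + i * self.pitch

    @property
    def span(self) -> tuple[float, float]:
        """(k_min, k_max) of the contact-bearing segment along the lead."""
        return (
            self.tip_to_first_contact,
            self.tip_to_first_contact
            + self.n_contacts * self.contact_length
            + (self.n_contacts - 1) * self.contact_gap,
        )


#: Medtronic model 3389 quadripolar lead.  The 1.5 mm distal-tip offset is
#: a packaged assumption, configurable via ``tip_to_first_contact``.
MODEL_3389 = LeadGeometry()


@dataclass(frozen=True)
class ContactSet:
    """The reconstructed contact centers of one lead.

    ``centers[0]`` is the most distal contact.  ``active_point`` and the
    parsed ``contact_indices_used`` are filled once a stimulation
    configuration is applied.
    """

    centers: np.ndarray  # (n_contacts, 3)
    observation: LeadObservation
    geometry: LeadGeometry
    active_point: np.ndarray | None = None
    active_config: str | None = None
    contact_indices_used: tuple[int, ...] = field(default_factory=tuple)


def lead_direction(obs: LeadObservation) -> np.ndarray:
    """Unit direction vector from tip toward shaft (pointing dorsally)."""
    d = obs.shaft - obs.tip
    n = float(np.linalg.norm(d))
    if n == 0.0:
        raise InvalidObservationError("tip and shaft coincide")
    return d / n


def contact_centers(obs: LeadObservation, geom: LeadGeometry = MODEL_3389) -> ContactSet:
    """Place the contact centers on the reconstructed lead line.

    The center of contact i sits at
    ``T + (tip_to_first_contact + contact_length/2 + i*pitch) * u``.
    """
    u = lead_direction(obs)
    ks = np.array([geom.contact_center_offset(i) for i in range(geom.n_contacts)])
    centers = obs.tip[None, :] + ks[:, None] * u[None, :]
    return ContactSet(centers=centers, observation=obs, geometry=geom)


_MONOPOLAR = re.compile(r"^c\+\s*(\d+)-$")
_BIPOLAR = re.compile(r"^(\d+)-(\d+)\+$")


def parse_active_config(config: str, n_contacts: int = 4) -> tuple[int, ...]:
    """Map a stimulation configuration label to within-lead contact indices.

    Two label families occur on bilateral implants:

    * monopolar, ``"c+ 3-"``: the pulse-generator case is the anode and
      contact 3 the (active) cathode;
    * bipolar, ``"1-2+"``: two adjacent contacts stimulated.

    Pulse generators number the contacts of multiple leads in blocks of
    four (0-3, 4-7, 8-11, 12-15), so labels are reduced modulo 4.  Unicode
    en-dashes are accepted.  Bipolar pairs must be adjacent after
    reduction.
    """
    text = config.strip().replace("–", "-").replace("−", "-")
    m = _MONOPOLAR.match(text)
    if m:
        idx = int(m.group(1)) % n_contacts
        return (idx,)
    m = _BIPOLAR.match(text)
    if m:
        a, b = int(m.group(1)), int(m.group(2))
        if a // n_contacts != b // n_contacts:
            raise InvalidConfigError(
                f"{config!r}: contacts belong to different leads"
            )
        ia, ib = a % n_contacts, b % n_contacts
        if abs(ia - ib) != 1:
            raise InvalidConfigError(f"{config!r}: contacts are not adjacent")
        return tuple(sorted((ia, ib)))
    raise InvalidConfigError(f"unrecognized stimulation configuration {config!r}")


def active_contact_point(contacts: ContactSet, config: str) -> ContactSet:
    """Derive the active-contact point from a stimulation configuration.

    A single stimulated contact contributes its own center; for two
    adjacent stimulated contacts the geometric center (midpoint) of the
    two contact centers is used.
    """
    indices = parse_active_config(config, contacts.geometry.n_contacts)
    for i in indices:
        if not 0 <= i < len(contacts.centers):
            raise InvalidConfigError(f"contact index {i} out of range")
    point = contacts.centers[list(indices)].mean(axis=0)
    return ContactSet(
        centers=contacts.centers,
        observation=contacts.observation,
        geometry=contacts.geometry,
        active_point=point,
        active_config=config,
        contact_indices_used=indices,
    )


def read_leads(path) -> list[tuple[LeadObservation, str]]:
    """Read a lead CSV into observations plus their configuration labels.

    Expected columns: patient_id, hemisphere, tip_x/y/z, shaft_x/y/z,
    active_config.
    """
    df = pd.read_csv(path)
    out: list[tuple[LeadObservation, str]] = []
    for _, row in df.iterrows():
        obs = LeadObservation(
            tip=[row["tip_x"], row["tip_y"], row["tip_z"]],
            shaft=[row["shaft_x"], row["shaft_y"], row["shaft_z"]],
            hemisphere=row["hemisphere"],
            patient_id=str(row["patient_id"]),
        )
        out.append((obs, str(row["active_config"])))
    return out
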
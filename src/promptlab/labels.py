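"""The closed activity set and its canonical ordering.

Four activity classes are recognized: standing still, walking, jogging and
riding a bus. The tuple order is fixed and doubles as the tie-break order
wherever two classes score identically.
"""

STANDING = "standing_still"
WALKING = "walking"
JOGGING = "jogging"
BUS = "bus"

#: Canonical class order (also the classifier tie-break order).
ACTIVITIES: tuple[str, ...] = (STANDING, WALKING, JOGGING, BUS)

#: Activities that can precede a prompt (everything except standing still).
MOVING: tuple[str, ...] = (WALKING, JOGGING, BUS)


def check_label(label: str) -> str:
    if label not in ACTIVITIES:
        raise ValueError(f"unknown activity label {label!r}; expected one of {ACTIVITIES}")
    return label
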
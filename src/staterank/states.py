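"""Normalization between full US state names (as printed in survey tables)
and USPS two-letter codes. The District of Columbia is included as a
"state" throughout, matching state-level surveillance reporting."""

from __future__ import annotations

STATE_TO_ABBREV: dict[str, str] = {
    "Alabama": "AL", "Alaska": "AK", "Arizona": "AZ", "Arkansas": "AR",
    "California": "CA", "Colorado": "CO", "Connecticut": "CT", "Delaware": "DE",
    "District of Columbia": "DC", "Florida": "FL", "Georgia": "GA",
    "Hawaii": "HI", "Idaho": "ID", "Illinois": "IL", "Indiana": "IN",
    "Iowa": "IA", "Kansas": "KS", "Kentucky": "KY", "Louisiana": "LA",
    "Maine": "ME", "Maryland": "MD", "Massachusetts": "MA", "Michigan": "MI",
    "Minnesota": "MN", "Mississippi": "MS", "Missouri": "MO", "Montana": "MT",
    "Nebraska": "NE", "Nevada": "NV", "New Hampshire": "NH", "New Jersey": "NJ",
    "New Mexico": "NM", "New York": "NY", "North Carolina": "NC",
    "North Dakota": "ND", "Ohio": "OH", "Oklahoma": "OK", "Oregon": "OR",
    "Pennsylvania": "PA", "Rhode Island": "RI", "South Carolina": "SC",
    "South Dakota": "SD", "Tennessee": "TN", "Texas": "TX", "Utah": "UT",
    "Vermont": "VT", "Virginia": "VA", "Washington": "WA",
    "West Virginia": "WV", "Wisconsin": "WI", "Wyoming": "WY",
}

ABBREV_TO_STATE: dict[str, str] = {v: k for k, v in STATE_TO_ABBREV.items()}


def to_abbrev(name: str) -> str:
    """Two-letter code for a full state name; codes pass through unchanged."""
    if name in ABBREV_TO_STATE:
        return name
    try:
        return STATE_TO_ABBREV[name]
    except KeyError:
        raise KeyError(f"unknown state name: {name!r}") from None


def to_full(abbrev: str) -> str:
    """Full state name for a two-letter code; full names pass through."""
    if abbrev in STATE_TO_ABBREV:
        return abbrev
    try:
        return ABBREV_TO_STATE[abbrev]
    except KeyError:
        raise KeyError(f"unknown state code: {abbrev!r}") from None
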
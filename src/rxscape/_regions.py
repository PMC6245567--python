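"""US state-code lookups: federal (HHS/GSA) regions and census regions."""

from __future__ import annotations

FEDERAL_REGIONS: dict[str, str] = {}
for _region, _states in {
    "Region 1": ["CT", "ME", "MA", "NH", "RI", "VT"],
    "Region 2": ["NJ", "NY", "PR", "VI"],
    "Region 3": ["DE", "DC", "MD", "PA", "VA", "WV"],
    "Region 4": ["AL", "FL", "GA", "KY", "MS", "NC", "SC", "TN"],
    "Region 5": ["IL", "IN", "MI", "MN", "OH", "WI"],
    "Region 6": ["AR", "LA", "NM", "OK", "TX"],
    "Region 7": ["IA", "KS", "MO", "NE"],
    "Region 8": ["CO", "MT", "ND", "SD", "UT", "WY"],
    "Region 9": ["AZ", "CA", "HI", "NV", "AS", "GU", "MP"],
    "Region 10": ["AK", "ID", "OR", "WA"],
}.items():
    for _s in _states:
        FEDERAL_REGIONS[_s] = _region

CENSUS_REGIONS: dict[str, str] = {}
for _region, _states in {
    "Northeast": ["CT", "ME", "MA", "NH", "RI", "VT", "NJ", "NY", "PA"],
    "Midwest": ["IL", "IN", "MI", "OH", "WI", "IA", "KS", "MN", "MO", "NE", "ND", "SD"],
    "South": ["DE", "DC", "FL", "GA", "MD", "NC", "SC", "VA", "WV",
              "AL", "KY", "MS", "TN", "AR", "LA", "OK", "TX", "PR", "VI"],
    "West": ["AZ", "CO", "ID", "MT", "NV", "NM", "UT", "WY",
             "AK", "CA", "HI", "OR", "WA", "AS", "GU", "MP"],
}.items():
    for _s in _states:
        CENSUS_REGIONS[_s] = _region


def resolve_region(state: str, level: str) -> str | None:
    """Map a 2-letter state code to a region label; None if unknown."""
    if level == "state":
        return state
    if level == "federal_region":
        return FEDERAL_REGIONS.get(state)
    if level == "census_region":
        return CENSUS_REGIONS.get(state)
    raise ValueError(f"unknown region level {level!r}")
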
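"""Region-code normalization.

Join keys are USPS two-letter codes for US states (DC included) and
ISO-3166-1 alpha-2 codes for countries.  Display names map to codes;
the original display string is kept alongside the code wherever tables
carry both.
"""

from __future__ import annotations

US_STATES: dict[str, str] = {
    "Alabama": "AL", "Alaska": "AK", "Arizona": "AZ", "Arkansas": "AR",
    "California": "CA", "Colorado": "CO", "Connecticut": "CT",
    "Delaware": "DE", "District of Columbia": "DC", "Florida": "FL",
    "Georgia": "GA", "Hawaii": "HI", "Idaho": "ID", "Illinois": "IL",
    "Indiana": "IN", "Iowa": "IA", "Kansas": "KS", "Kentucky": "KY",
    "Louisiana": "LA", "Maine": "ME", "Maryland": "MD",
    "Massachusetts": "MA", "Michigan": "MI", "Minnesota": "MN",
    "Mississippi": "MS", "Missouri": "MO", "Montana": "MT",
    "Nebraska": "NE", "Nevada": "NV", "New Hampshire": "NH",
    "New Jersey": "NJ", "New Mexico": "NM", "New York": "NY",
    "North Carolina": "NC", "North Dakota": "ND", "Ohio": "OH",
    "Oklahoma": "OK", "Oregon": "OR", "Pennsylvania": "PA",
    "Rhode Island": "RI", "South Carolina": "SC", "South Dakota": "SD",
    "Tennessee": "TN", "Texas": "TX", "Utah": "UT", "Vermont": "VT",
    "Virginia": "VA", "Washington": "WA", "West Virginia": "WV",
    "Wisconsin": "WI", "Wyoming": "WY",
}

COUNTRIES: dict[str, str] = {
    "Algeria": "DZ", "Argentina": "AR", "Australia": "AU",
    "Bangladesh": "BD", "Belgium": "BE", "Bolivia": "BO", "Brazil": "BR",
    "Canada": "CA", "Chile": "CL", "Colombia": "CO", "Costa Rica": "CR",
    "Denmark": "DK", "Dominican Republic": "DO", "Ecuador": "EC",
    "Egypt": "EG", "France": "FR", "Germany": "DE", "Ghana": "GH",
    "Guatemala": "GT", "India": "IN", "Indonesia": "ID", "Ireland": "IE",
    "Italy": "IT", "Japan": "JP", "Kenya": "KE", "Malaysia": "MY",
    "Mexico": "MX", "Morocco": "MA", "New Zealand": "NZ", "Nigeria": "NG",
    "Norway": "NO", "Pakistan": "PK", "Panama": "PA", "Paraguay": "PY",
    "Peru": "PE", "Philippines": "PH", "Poland": "PL", "Portugal": "PT",
    "Puerto Rico": "PR", "Romania": "RO", "Russian Federation": "RU",
    "Saudi Arabia": "SA", "Singapore": "SG", "South Africa": "ZA",
    "Spain": "ES", "Sweden": "SE", "Switzerland": "CH", "Thailand": "TH",
    "Turkey": "TR", "United Arab Emirates": "AE", "United Kingdom": "GB",
    "United States": "US", "United States of America": "US",
    "Uruguay": "UY", "Viet Nam": "VN", "Vietnam": "VN",
}


def normalize_region(name: str) -> str:
    """Map a display name to its region code; pass codes through unchanged.

    Unknown names are returned as-is so ad-hoc region keys still work as
    join keys (normalization is a convenience, not a gate).
    """
    name = name.strip()
    if name in US_STATES:
        return US_STATES[name]
    if name in COUNTRIES:
        return COUNTRIES[name]
    return name
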
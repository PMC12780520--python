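"""Country -> global-region lookup for the 62 LMICs covered by the analysis.

Six regions: Central Asia (CA), Latin America & the Caribbean (LAC),
North Africa, West Asia & Europe (NAWAE), Oceania, South Asia & Southeast
Asia (SASEA), and Sub-Saharan Africa (SSA), following WHO / World Bank
groupings.
"""

from __future__ import annotations

from typing import Dict

__all__ = ["REGIONS", "COUNTRY_REGION", "map_country_region", "UnknownCountryError"]

REGIONS = ("CA", "LAC", "NAWAE", "Oceania", "SASEA", "SSA")

_REGION_COUNTRIES: Dict[str, tuple] = {
    "CA": ("Kyrgyz Republic", "Tajikistan"),
    "LAC": (
        "Bolivia", "Colombia", "Dominican Republic", "Guatemala",
        "Guyana", "Haiti", "Honduras", "Peru",
    ),
    "NAWAE": (
        "Albania", "Armenia", "Azerbaijan", "Egypt", "Jordan", "Turkey", "Yemen",
    ),
    "Oceania": ("Papua New Guinea",),
    "SASEA": (
        "Bangladesh", "Cambodia", "India", "Maldives", "Myanmar",
        "Nepal", "Pakistan", "Timor-Leste",
    ),
    "SSA": (
        "Angola", "Benin", "Burkina Faso", "Burundi", "Cameroon", "Chad",
        "Comoros", "Congo", "Congo Democratic Republic", "Cote d'Ivoire",
        "Eswatini", "Ethiopia", "Gabon", "Gambia", "Ghana", "Guinea",
        "Kenya", "Lesotho", "Liberia", "Madagascar", "Malawi", "Mali",
        "Mauritania", "Mozambique", "Namibia", "Niger", "Nigeria",
        "Rwanda", "Sao Tome and Principe", "Senegal", "Sierra Leone",
        "South Africa", "Togo", "Uganda", "Zambia", "Zimbabwe",
    ),
}

COUNTRY_REGION: Dict[str, str] = {
    country: region for region, countries in _REGION_COUNTRIES.items() for country in countries
}
assert len(COUNTRY_REGION) == 62


class UnknownCountryError(KeyError):
    """Raised for a country outside the 62-country lookup."""

    def __init__(self, country: str):
        valid = ", ".join(sorted(COUNTRY_REGION))
        super().__init__(f"unknown country {country!r}; valid names: {valid}")
        self.country = country


def map_country_region(country: str) -> str:
    """Region code for ``country`` (case-insensitive exact name match)."""
    if country in COUNTRY_REGION:
        return COUNTRY_REGION[country]
    folded = {k.casefold(): v for k, v in COUNTRY_REGION.items()}
    key = str(country).casefold()
    if key in folded:
        return folded[key]
    raise UnknownCountryError(country)
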
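"""Body-site vocabulary for HMP-style sample metadata.

The 16S surveys this package targets sample 18 body sites grouped into five
body locations (airways, gut, oral, skin, urogenital). The vocabulary is
configuration, not a hard constraint: unknown sites are accepted and mapped
to location ``"other"`` with a logged warning.
"""

from __future__ import annotations

import logging

logger = logging.getLogger(__name__)

#: site -> body location, seeded with the 18 HMP sites / 5 locations.
BODY_SITES: dict[str, str] = {
    "Anterior nares": "airways",
    "Stool": "gut",
    "Attached Keratinized gingiva": "oral",
    "Buccal mucosa": "oral",
    "Hard palate": "oral",
    "Palatine Tonsils": "oral",
    "Saliva": "oral",
    "Subgingival plaque": "oral",
    "Supragingival plaque": "oral",
    "Throat": "oral",
    "Tongue dorsum": "oral",
    "Left Antecubital fossa": "skin",
    "Left Retroauricular crease": "skin",
    "Right Antecubital fossa": "skin",
    "Right Retroauricular crease": "skin",
    "Mid vagina": "urogenital",
    "Posterior fornix": "urogenital",
    "Vaginal introitus": "urogenital",
}

BODY_LOCATIONS = ("airways", "gut", "oral", "skin", "urogenital")

_CANONICAL = {site.casefold(): site for site in BODY_SITES}


def canonical_site(site: str) -> str:
    """Return the canonical spelling of ``site`` (case-insensitive), or the
    input unchanged if the site is not in the vocabulary."""
    return _CANONICAL.get(site.strip().casefold(), site.strip())


def location_for_site(site: str) -> str:
    """Map a body site to its body location.

    Unknown sites yield ``"other"`` and a warning in the package log; they are
    never an error, so surveys over tables with novel site labels complete.
    """
    canon = canonical_site(site)
    try:
        return BODY_SITES[canon]
    except KeyError:
        logger.warning("unknown body site %r; assigning location 'other'", site)
        return "other"
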
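"""Package-wide defaults.

Every number here is a default, not a constant of the method: the GRADE
certainty-to-multiplier mapping is explicitly open to debate, and the
strong/weak preference-share boundaries operationalise verbal definitions
that carry no agreed numeric values.  All of them can be overridden per
call and every report states the values actually used.
"""

from __future__ import annotations

#: Default mapping from GRADE certainty-of-evidence levels to the [0, 1]
#: multiplier used in certainty-adjusted scoring.
DEFAULT_CERTAINTY_MULTIPLIERS: dict[str, float] = {
    "very_low": 0.1,
    "low": 0.4,
    "moderate": 0.7,
    "high": 1.0,
}

#: Preference-share boundaries for classifying how preference-sensitive a
#: decision is.  A share of simulated informed patients >= ``strong`` for one
#: option maps to ``strong_for`` that option; >= ``weak`` to ``weak_for``;
#: anything else is equipoise.  These are working defaults for a verbal
#: concept ("most informed patients") and must be surfaced wherever used.
DEFAULT_STRONG_THRESHOLD: float = 0.9
DEFAULT_WEAK_THRESHOLD: float = 0.6

#: Default certainty-adjustment mode; see :mod:`decisio.scoring`.
DEFAULT_ADJUSTMENT_MODE: str = "multiplicative"

#: Disclaimer carried by every model document and every rendered report.
DISCLAIMER: str = (
    "This tool is not a validated clinical decision aid. The scores it "
    "produces are preference-sensitive opinions intended to support "
    "discussion; they are not directives, and no representation is made "
    "that the underlying evidence values are accurate or up to date. Any "
    "reliance placed on this output is strictly at the user's own risk."
)
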
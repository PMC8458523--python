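"""Published hour counts used as fixed inputs by the accounting checks.

These are the source study's printed per-category hour counts (hours with
exclusively social calls, hours with complex song HWS1, hours with
preliminary song HWS2) and the printed total of hours verified to contain
vocalizations.  They are data, not results computed here.
"""

SOCIAL_ONLY_HOURS = 3239
HWS1_HOURS = 1127
HWS2_HOURS = 430

#: Printed total of verified vocalization hours.
TOTAL_VOCALIZATION_HOURS = 4796

CATEGORY_HOUR_COUNTS = {
    "social_only": SOCIAL_ONLY_HOURS,
    "hws1": HWS1_HOURS,
    "hws2": HWS2_HOURS,
}
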
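"""Integer codes for male reproductive states shared across the whole pipeline."""

SUBORDINATE = 0
SNEAKER = 1
GUARD = 2
DEAD = 3

STATE_NAMES = {SUBORDINATE: "subordinate", SNEAKER: "sneaker", GUARD: "guard", DEAD: "dead"}
NAME_TO_STATE = {v: k for k, v in STATE_NAMES.items()}

#: live states a male can occupy during an oestrus event
LIVE_STATES = (SUBORDINATE, SNEAKER, GUARD)
#: non-reference multinomial destinations (subordinate is the reference)
NONREF_DESTS = (SNEAKER, GUARD)
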
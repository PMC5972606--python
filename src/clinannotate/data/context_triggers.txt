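# Default English context trigger lexicon.
# Format: phrase|category|role|direction
#   category  ∈ negation, experiencer_other, historical, hypothetical
#   role      ∈ trigger, pseudo, termination   (default: trigger)
#   direction ∈ forward, backward, both        (default: forward)
# Distilled from the public NegEx/ConText term lists; replace freely.

# ---- negation: forward triggers ----
no|negation|trigger|forward
not|negation|trigger|forward
without|negation|trigger|forward
denies|negation|trigger|forward
denied|negation|trigger|forward
denying|negation|trigger|forward
no sign of|negation|trigger|forward
no signs of|negation|trigger|forward
no evidence of|negation|trigger|forward
no evidence for|negation|trigger|forward
no suggestion of|negation|trigger|forward
no complaints of|negation|trigger|forward
no history of|negation|trigger|forward
no new|negation|trigger|forward
absence of|negation|trigger|forward
absent|negation|trigger|forward
negative for|negation|trigger|forward
never had|negation|trigger|forward
never developed|negation|trigger|forward
free of|negation|trigger|forward
lack of|negation|trigger|forward
lacks|negation|trigger|forward
rules out|negation|trigger|forward
rule out|negation|trigger|forward
ruled out for|negation|trigger|forward
rule him out for|negation|trigger|forward
rule her out for|negation|trigger|forward
cannot identify|negation|trigger|forward
fails to reveal|negation|trigger|forward
declined|negation|trigger|forward
declines|negation|trigger|forward
resolved|negation|trigger|forward
unremarkable for|negation|trigger|forward
with no|negation|trigger|forward
rather than|negation|trigger|forward

# ---- negation: backward triggers ----
unlikely|negation|trigger|backward
is ruled out|negation|trigger|backward
are ruled out|negation|trigger|backward
was ruled out|negation|trigger|backward
were ruled out|negation|trigger|backward
has been ruled out|negation|trigger|backward
have been ruled out|negation|trigger|backward
is negative|negation|trigger|backward
was negative|negation|trigger|backward
is absent|negation|trigger|backward
was absent|negation|trigger|backward
is excluded|negation|trigger|backward
not present|negation|trigger|backward
free|negation|trigger|backward

# ---- negation: pseudo phrases (suppress a trigger reading) ----
no increase|negation|pseudo|forward
no change|negation|pseudo|forward
no definite change|negation|pseudo|forward
no interval change|negation|pseudo|forward
no significant change|negation|pseudo|forward
no suspicious change|negation|pseudo|forward
no further|negation|pseudo|forward
not extend|negation|pseudo|forward
not cause|negation|pseudo|forward
not certain if|negation|pseudo|forward
not certain whether|negation|pseudo|forward
not necessarily|negation|pseudo|forward
not rule out|negation|pseudo|forward
not ruled out|negation|pseudo|forward
not been ruled out|negation|pseudo|forward
without difficulty|negation|pseudo|forward
gram negative|negation|pseudo|forward
not only|negation|pseudo|forward
not drain|negation|pseudo|forward

# ---- experiencer: family / other persons (forward) ----
mother|experiencer_other|trigger|forward
mother's|experiencer_other|trigger|forward
father|experiencer_other|trigger|forward
father's|experiencer_other|trigger|forward
mom|experiencer_other|trigger|forward
dad|experiencer_other|trigger|forward
brother|experiencer_other|trigger|forward
sister|experiencer_other|trigger|forward
sibling|experiencer_other|trigger|forward
siblings|experiencer_other|trigger|forward
aunt|experiencer_other|trigger|forward
uncle|experiencer_other|trigger|forward
grandmother|experiencer_other|trigger|forward
grandfather|experiencer_other|trigger|forward
grandparent|experiencer_other|trigger|forward
grandparents|experiencer_other|trigger|forward
cousin|experiencer_other|trigger|forward
wife|experiencer_other|trigger|forward
husband|experiencer_other|trigger|forward
son|experiencer_other|trigger|forward
daughter|experiencer_other|trigger|forward
family history of|experiencer_other|trigger|forward
family history|experiencer_other|trigger|forward
family member|experiencer_other|trigger|forward
family members|experiencer_other|trigger|forward

# ---- temporality: historical (forward) ----
history of|historical|trigger|forward
history|historical|trigger|forward
past history of|historical|trigger|forward
past medical history of|historical|trigger|forward
past medical history|historical|trigger|forward
previous|historical|trigger|forward
previously|historical|trigger|forward
prior|historical|trigger|forward
status post|historical|trigger|forward
childhood|historical|trigger|forward
preoperative|historical|trigger|forward
in the past|historical|trigger|backward
years ago|historical|trigger|backward
as a child|historical|trigger|backward

# ---- temporality: historical pseudo ----
poor history|historical|pseudo|forward
social history|historical|pseudo|forward
history taking|historical|pseudo|forward
history and physical|historical|pseudo|forward

# ---- temporality: hypothetical (forward) ----
if|hypothetical|trigger|forward
if negative|hypothetical|pseudo|forward
return|hypothetical|trigger|forward
should|hypothetical|trigger|forward
should there be|hypothetical|trigger|forward
in case|hypothetical|trigger|forward
in case of|hypothetical|trigger|forward
come back|hypothetical|trigger|forward
come back for|hypothetical|trigger|forward
as needed|hypothetical|trigger|forward
watch for|hypothetical|trigger|forward
monitor for|hypothetical|trigger|forward
risk of|hypothetical|trigger|forward
risk for|hypothetical|trigger|forward
could be|hypothetical|trigger|forward

# ---- termination terms (close a scope; category ignored) ----
but|negation|termination|forward
however|negation|termination|forward
nevertheless|negation|termination|forward
yet|negation|termination|forward
though|negation|termination|forward
although|negation|termination|forward
aside from|negation|termination|forward
apart from|negation|termination|forward
except|negation|termination|forward
still|negation|termination|forward
which|negation|termination|forward
other than|negation|termination|forward
secondary to|negation|termination|forward
as the cause of|negation|termination|forward
as a cause of|negation|termination|forward
reason for|negation|termination|forward
reasons for|negation|termination|forward
cause of|negation|termination|forward
causes of|negation|termination|forward
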
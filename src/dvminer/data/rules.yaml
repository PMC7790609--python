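# Declarative rule templates for role attribution of mental-illness mentions.
#
# Attribution is sentence-scoped: a dictionary hit is attributed to the role of
# the nearest semantic anchor in the same sentence (ties favour the anchor that
# precedes the hit).  Trigger phrases are optional context; when one occurs
# between narrative start and the hit it is recorded in the pattern id for
# auditing, otherwise the pattern id is "<role>:anchor_only".
anchors:
  POI:
    - poi
    - defendant
    - accused
    - offender
    - perpetrator
  VICTIM:
    - victim
    - vic
triggers:
  suffering_from: "suffering from"
  suffers_from: "suffers from"
  diagnosed_with: "diagnosed with"
  diagnosis_of: "diagnosis of"
  history_of: "history of"
  known_to_have: "known to have"
  treated_for: "treated for"
  has: "has"
  had: "had"
  have: "have"
  takes: "takes"
  taking: "taking"
  is_on: "is on"
  was_on: "was on"
  are_on: "are on"
  prescribed: "prescribed"
  uses: "uses"
  presents_with: "presents with"
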
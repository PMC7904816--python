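# Curated tree pattern expressions for microbe-disease relation triplets.
# Captures: 1# microbe (BAC00...), 2# disease (DIS00...), 3# relation word.
# Grammar: {LABEL_RE item*} internal node, <POS_RE WORD_RE> leaf,
#          * one arbitrary subtree, ** gap of zero or more subtrees.
#
# appositive_comma: a tagged microbe NP followed by a comma-delimited
# appositive NP whose head noun is the relation word and whose PP holds
# the tagged disease ("BAC00X , a common cause of DIS00Y , ...").
# Published form (typeset with spacing artifacts):
#   {.*+ ** {NP ** <N.*+ 1#BAC00.*+> **} <, ,> {NP ** <N.*+ 3#.*+> {PP <IN **> ** {NP ** <N.*+ 2#DIS00.*+> **}}} <, ,> **}
appositive_comma	{.+ ** {NP ** <N.+ 1#BAC00.+> **} <, ,> {NP ** <N.+ 3#.+> {PP <IN .+> ** {NP ** <N.+ 2#DIS00.+> **}}} <, ,> **}
#
# passive_participle: passive clause with a past participle as the
# relation word and the tagged disease inside its PP
# ("BAC00X is associated with DIS00Y").
# Published form (typeset with bracket artifacts and without captures):
#   {S * {NP * <N.+ BAC00.+> *} * <VP <VBN .+> * <PP <IN *> * {NP * <N.+ DIS00.+> *} *> *> *}
passive_participle	{S ** {NP ** <N.+ 1#BAC00.+> **} ** {VP ** <VBN 3#.+> ** {PP <IN .+> ** {NP ** <N.+ 2#DIS00.+> **}} **} **}
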
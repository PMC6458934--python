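# BNF grammar generating partially connected three-layer SNN descriptions.
#
# A word is a sequence of hidden-neuron blocks, each terminated by "{".
# Within a block, "("-terminated synapse configurations connect input
# neurons to the hidden neuron; the final configuration (no trailing "(")
# is the hidden neuron's synapse onto the single output neuron.  Each
# configuration reads  id @ weight @ delay.  Weight literals span
# [-999.99, 999.99]; delay literals are clamped into [0.01, 19.99] at
# parse time; neuron identifiers are reduced modulo the input count.

<architecture> ::= <hidden> | <hidden> <architecture>
<hidden>       ::= <insyns> <outsyn> "{"
<insyns>       ::= <insyn> | <insyn> <insyns>
<insyn>        ::= <id> "@" <weight> "@" <delay> "("
<outsyn>       ::= "0" "@" <weight> "@" <delay>
<id>           ::= <digit> | <digit> <digit>
<weight>       ::= <sign> <wmag> "." <digit> <digit>
<sign>         ::= "" | "-"
<wmag>         ::= <digit> | <digit> <digit> | <digit> <digit> <digit>
<delay>        ::= <dmag> "." <digit> <digit>
<dmag>         ::= <digit> | <digit> <digit>
<digit>        ::= "0" | "1" | "2" | "3" | "4" | "5" | "6" | "7" | "8" | "9"
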
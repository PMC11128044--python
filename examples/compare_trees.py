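"""Quartet congruence between two topologies, polytomies included.

Compares a partly unresolved consensus-style tree against a fully binary
reference: the status counts separate genuine conflict (d) from mere lack
of resolution (r2 here), which Robinson-Foulds distances conflate.
"""

from scoutknife import parse_newick, quartet_status, similarity_metrics

consensus = parse_newick("((A,B),(C,D),E,(F,(G,H)));")      # one polytomy
reference = parse_newick("(((A,B),(C,D)),(E,(F,(G,H))));")  # fully resolved

status = quartet_status(consensus, reference)
print(f"quartets Q={status.Q}: s={status.s} d={status.d} "
      f"r1={status.r1} r2={status.r2} u={status.u}")
for name, value in similarity_metrics(status).items():
    print(f"  {name:32s} {value:.4f}")

# do_not_conflict = 1.0 with explicitly_agree < 1 is the signature of a
# conservative consensus: nothing contradicts the reference, but some
# relationships are left as polytomies rather than asserted.
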
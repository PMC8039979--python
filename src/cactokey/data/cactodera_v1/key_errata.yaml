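# Errata and repairs applied while transcribing the printed genus key into
# key.yaml, plus known tensions between the printed key and the comparative
# matrix that the audit (`cactokey key validate`) is expected to surface.
version: cactodera_v1
repairs:
  - couplet: 1
    kind: predicate-encoding
    note: >
      The printed first lead reads "two times or more longer than wide, mean
      L/W ratio = 2.3" and the alternative "mean L/W ratio = 1.1-1.8". These
      point/range statements are not complementary; they are encoded as the
      complementary mean threshold ">= 2.0" vs "< 2.0" implied by "two times
      or more longer than wide".
  - couplet: 11
    kind: dangling-target
    note: >
      The printed first lead "Mean J2s tail length < 40 um ... 11"
      self-references its own couplet; repaired to point to couplet 12.
      The second lead's target is repaired to couplet 14, consistent with
      the downstream couplets separating C. amaranthi / C. torreyanae /
      C. salina from C. acnidae / C. radicale / C. weissi / C. tianzhuensis.
  - couplet: 14
    kind: ambiguous-basis
    note: >
      The lead tests "DGO = 4.5-5.6 um" yet C. tianzhuensis spans 4.0-6.5 um.
      Whether a mean test was intended is unknowable; it is evaluated as a
      range test with ambiguity allowed, so the new species still reaches
      couplet 15 via an ambiguous (not failed) step.
known_misroutes:
  # Taxa whose own matrix row does not route them to their terminal when the
  # key's mean tests are answered with interval midpoints (the matrix stores
  # ranges only, so midpoints stand in for unpublished means). These are
  # properties of the printed key versus the comparative table, reported by
  # the audit rather than silently repaired.
  - taxon: C. torreyanae
    couplet: 1
    note: >
      Cyst L/W range 1.4-2.9 has midpoint 2.15 >= 2.0, so the midpoint proxy
      routes C. torreyanae to the C. estonica terminal at couplet 1. The
      published mean L/W of C. torreyanae is presumably below 2; the matrix
      stores only the range, and the midpoint of a skewed range is a poor
      stand-in for the mean.
  - taxon: C. solani
    couplet: 6
    note: >
      Cyst width range 204-505 um has midpoint 354.5 > 325 um, failing the
      "mean cyst width <= 325 um" conjunct of the C. solani lead, while the
      first lead fails on mean tail length (midpoint 38.5 <= 40 um): a
      dead-end under the midpoint proxy. The printed key and the comparative
      table are in tension for this species.
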
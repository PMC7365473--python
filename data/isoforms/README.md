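# Heavy-chain sequences (not shipped)

Sequence databases cannot be redistributed here, so this directory starts
empty.  On a networked machine run, from the repository root:

    python scripts/fetch_sequences.py

It downloads the four heavy chains used for the NM2/M18A analyses —
NM2A (UniProt P35579), NM2B (P35580), NM2C (RefSeq NP_079005) and
M18A (Q92614) — into `isoforms.fasta` and writes `isoforms.yaml` with
default rod annotations (rod interval, fallback heptad phase, empty skip
list).  For production work replace the fallback register with a
paircoil-derived per-residue register TSV (`register_file` in the YAML)
and set the skip positions.

Sequence-scale tests in `tests/test_acceptance.py` activate automatically
once `isoforms.yaml` exists.
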
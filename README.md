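# readthrough

Strand-specific meta-gene analysis of transcriptional read-through
downstream of transcript 3' ends, from bulk stranded RNA-seq coverage.

When RNAPII transcription termination fails — for example when the
5'→3' "torpedo" exoribonuclease XRN2 is catalytically dead — RNA
accumulates downstream of the expected termination site. This package
quantifies that accumulation for people comparing termination competence
between conditions (wild-type vs mutant, treated vs untreated): it
anchors every highly expressed (TPM > 10), spliced transcript at its 3'
end (TES), sums strand-specific signal in K contiguous 250-nt genomic
windows placed directly downstream, normalizes each window to the signal
in the last 250 nt of the transcript, and averages across transcripts
into a meta-gene profile per condition and replicate. For transcript t
and window k the statistic is

    r_t(k) = S_t(k) / S_t(term),   k = 1..K

where S_t(k) is the coverage sum in the k-th W-nt window downstream of
the TES and S_t(term) the sum in the terminal W nt of the transcript;
the meta-gene curve is mean_t r_t(k) (a cumulative pooled-ratio mode is
also available). The terminal normalization cancels expression level and
depth, so condition curves overlay over the gene body and separate only
where termination differs. A seeded bootstrap contrasts two conditions
per window.

The package also ships a synthetic-data generator (stranded exonic
coverage with exponentially decaying read-through, Poisson noise, known
ground truth) so the whole pipeline is testable at desk scale, plus the
closed-form expectation of the statistic under that model.

## Worked example

Simulate a wild-type-like condition (read-through fraction α = 0.05) and
a termination-deficient one (α = 0.6), triplicate, 50 transcripts, then
run the full pipeline:

```
readthrough simulate --out demo --seed 42 --n-transcripts 50 --replicates 3 \
    --alpha WT=0.05 --alpha MUT=0.6
readthrough run-all demo/config.yaml --out out
```

The run log reports the filter audit (9 of 50 simulated transcripts are
monoexonic and excluded; the rest pass TPM > 10 and clearance):

```
INFO condition MUT: retained 41/50 transcripts (excluded: {'monoexonic': 9})
INFO condition WT: retained 41/50 transcripts (excluded: {'monoexonic': 9})
INFO run complete: out
```

`out/metagene.tsv` holds one meta-gene curve per condition and replicate
(and an across-replicate mean). First windows of MUT rep1:

```
condition  replicate  window_k  distance_nt  mean    sd      n   mode
MUT        rep1       1         0            0.5267  0.0216  41  mean_of_ratios
MUT        rep1       2         250          0.4134  0.0142  41  mean_of_ratios
MUT        rep1       3         500          0.3222  0.0140  41  mean_of_ratios
```

The window-1 mean ≈ 0.53 is the mutant's downstream signal at the TES,
about α·(λ/W)(1−e^(−W/λ)) = 0.6·0.885 = 0.53 for the simulated decay
length λ = 1000 nt — i.e. the generator's truth is recovered. The same
rows for WT sit near 0.044, and `out/comparison.tsv` quantifies the
contrast (difference MUT − WT per window with a seeded 1000-draw
bootstrap CI):

```
window_k  distance_nt  diff    ratio   ci_lo   ci_hi   n_boot  seed
1         0            0.4856  12.00   0.4819  0.4892  1000    42
2         250          0.3799  11.98   0.3776  0.3821  1000    42
```

Every window's CI excludes zero: the termination-deficient condition
accumulates downstream RNA the wild-type does not, while gene-body
(terminal-normalized) levels agree by construction. Reruns with the same
config and seed are byte-identical; `out/manifest.txt` records input
checksums, exclusion tallies, seed and version.

Subcommands `quantify`, `metagene` and `compare` run the stages
individually and compose to exactly the `run-all` output.

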
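# SYNTHETIC illustrative profiles for the auxiliary feature blocks:
# standard language scores (confrontation naming, repetition, single-word
# comprehension) and regional gray-matter volumes (head-size normalized,
# arbitrary volume units).  Group-level values for these blocks are not
# published; the numbers below are plausible-looking placeholders whose only
# purpose is to exercise the block machinery of the model grid.  They are NOT
# published values and must not be interpreted as such.
schema_version: 1
kind: auxiliary_synthetic
groups:
  HC:
    standard_language:
      naming:                    {mean: 94.0, sd: 5.0, min: 60.0, max: 100.0}
      repetition:                {mean: 145.0, sd: 4.0, min: 100.0, max: 150.0}
      single_word_comprehension: {mean: 98.0, sd: 2.0, min: 80.0, max: 100.0}
    gmv:
      l_sma:                  {mean: 10.0, sd: 1.0, min: 6.0, max: 14.0}
      l_insula:               {mean: 10.0, sd: 1.0, min: 6.0, max: 14.0}
      l_middle_temporal:      {mean: 10.0, sd: 1.0, min: 6.0, max: 14.0}
      l_middle_temporal_pole: {mean: 10.0, sd: 1.0, min: 6.0, max: 14.0}
      l_hippocampus:          {mean: 10.0, sd: 1.0, min: 6.0, max: 14.0}
      r_pars_opercularis:     {mean: 10.0, sd: 1.0, min: 6.0, max: 14.0}
  nfvPPA:
    standard_language:
      naming:                    {mean: 72.0, sd: 12.0, min: 20.0, max: 100.0}
      repetition:                {mean: 112.0, sd: 14.0, min: 60.0, max: 150.0}
      single_word_comprehension: {mean: 92.0, sd: 6.0, min: 60.0, max: 100.0}
    gmv:
      l_sma:                  {mean: 8.0, sd: 1.0, min: 4.0, max: 12.0}
      l_insula:               {mean: 8.6, sd: 1.0, min: 4.0, max: 12.0}
      l_middle_temporal:      {mean: 9.5, sd: 1.0, min: 5.0, max: 13.0}
      l_middle_temporal_pole: {mean: 9.4, sd: 1.0, min: 5.0, max: 13.0}
      l_hippocampus:          {mean: 9.3, sd: 1.0, min: 5.0, max: 13.0}
      r_pars_opercularis:     {mean: 8.2, sd: 1.0, min: 4.0, max: 12.0}
  svPPA:
    standard_language:
      naming:                    {mean: 42.0, sd: 14.0, min: 0.0, max: 90.0}
      repetition:                {mean: 136.0, sd: 8.0, min: 90.0, max: 150.0}
      single_word_comprehension: {mean: 72.0, sd: 10.0, min: 30.0, max: 95.0}
    gmv:
      l_sma:                  {mean: 9.5, sd: 1.0, min: 5.0, max: 13.0}
      l_insula:               {mean: 8.0, sd: 1.0, min: 4.0, max: 12.0}
      l_middle_temporal:      {mean: 7.6, sd: 1.0, min: 4.0, max: 11.0}
      l_middle_temporal_pole: {mean: 7.0, sd: 1.0, min: 3.5, max: 11.0}
      l_hippocampus:          {mean: 8.0, sd: 1.0, min: 4.0, max: 12.0}
      r_pars_opercularis:     {mean: 9.5, sd: 1.0, min: 5.0, max: 13.0}
  lvPPA:
    standard_language:
      naming:                    {mean: 66.0, sd: 12.0, min: 20.0, max: 100.0}
      repetition:                {mean: 98.0, sd: 15.0, min: 50.0, max: 140.0}
      single_word_comprehension: {mean: 90.0, sd: 6.0, min: 60.0, max: 100.0}
    gmv:
      l_sma:                  {mean: 9.5, sd: 1.0, min: 5.0, max: 13.0}
      l_insula:               {mean: 9.3, sd: 1.0, min: 5.0, max: 13.0}
      l_middle_temporal:      {mean: 8.4, sd: 1.0, min: 4.5, max: 12.0}
      l_middle_temporal_pole: {mean: 9.0, sd: 1.0, min: 5.0, max: 13.0}
      l_hippocampus:          {mean: 9.2, sd: 1.0, min: 5.0, max: 13.0}
      r_pars_opercularis:     {mean: 9.6, sd: 1.0, min: 5.0, max: 13.0}
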
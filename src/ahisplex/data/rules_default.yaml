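# Default classification rules (versioned, data-driven).
#
# This file is an explicit approximation of the official manual's decision
# tree: the category orders and vocabularies are the published ones, the
# threshold constants are this package's documented choices pending exact
# transcription from the manual.  Users holding the manual can edit this
# file (or ship a sibling) without touching code.
version: default-0.1
eye:
  order_light_to_dark: [blue, intermediate, brown]
  labels:
    blue: blue
    intermediate: intermediate
    brown: brown
hair:
  order_light_to_dark: [blond, red, brown, black]
  red_category: red
  shade_dark_category: dark
  thresholds:
    mild: 0.5
    strong: 0.7
    black: 0.9
  labels:
    red: red
    blond:
      base: blonde
      mild: dark-blonde/blonde
      strong: dark-blonde/brown
    brown:
      base: brown
      strong: dark-brown/brown
      black: dark-brown/black
    black:
      base: black
skin:
  order_light_to_dark: [very_pale, pale, intermediate, dark, dark_black]
  darker_tail_threshold: 0.3
  lighter_tail_threshold: 0.6
  labels:
    very_pale:
      base: very pale
      darker: very pale/darker
    pale:
      lighter: pale/lighter
      base: pale
      darker: pale/darker
    intermediate:
      lighter: intermediate/lighter
      base: intermediate
      darker: intermediate/darker
    dark:
      lighter: dark/lighter
      base: dark
      darker: dark/dark-black
    dark_black:
      base: dark-black
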
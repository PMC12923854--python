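# SYNTHETIC demo model for tests and examples.
#
# These multinomial-logistic coefficients are invented: signs follow the
# pigmentation literature (e.g. the rs12913832_T probe counts the
# brown-associated allele; MC1R loss-of-function probes push toward red
# hair; rs1426654_G / rs16891982_C push toward darker skin), but the
# numbers were NOT estimated from any phenotype data and must never be used
# for real prediction.  The published coefficient set is configuration the
# user supplies in this same schema.
version: demo-synthetic-1
groups:
  eye:
    categories: [blue, intermediate, brown]
    reference: blue
    coefficients:
      intermediate:
        intercept: -2.0
        rs12913832_T: 1.2
        rs1393350_A: 0.3
        rs12203592_T: 0.3
      brown:
        intercept: -4.0
        rs12913832_T: 2.8
        rs1129038_A: 0.5
        rs1800407_A: -0.8
        rs1393350_A: 0.4
  hair_colour:
    categories: [blond, brown, red, black]
    reference: blond
    coefficients:
      brown:
        intercept: -0.5
        rs12913832_T: 0.6
        rs683_G: 0.4
        rs12821256_G: -0.6
        rs12203592_T: 0.5
        rs1042602_A: -0.3
      red:
        intercept: -5.0
        rs312262906_A: 2.5
        rs11547464_A: 2.1
        rs1805005_T: 0.5
        rs1805006_A: 2.2
        rs1805007_T: 2.4
        rs1805008_T: 2.2
        rs1805009_C: 2.1
        rs201326893_A: 2.2
        rs1110400_C: 1.9
        rs885479_A: 0.3
        rs2228479_A: 0.3
      black:
        intercept: -2.5
        rs12913832_T: 1.0
        rs683_G: 0.7
        rs16891982_C: 0.9
        rs2402130_G: 0.4
  hair_shade:
    categories: [light, dark]
    reference: light
    coefficients:
      dark:
        intercept: -1.5
        rs12913832_T: 0.9
        rs683_G: 0.5
        rs16891982_C: 0.6
        rs1667394_C: -0.4
  skin:
    categories: [very_pale, pale, intermediate, dark, dark_black]
    reference: very_pale
    coefficients:
      pale:
        intercept: 1.0
        rs1426654_G: 0.5
        rs16891982_C: 0.4
      intermediate:
        intercept: 0.2
        rs1426654_G: 1.2
        rs16891982_C: 1.0
        rs1545397_T: 0.5
        rs6119471_C: 0.4
      dark:
        intercept: -1.5
        rs1426654_G: 2.2
        rs16891982_C: 1.8
        rs6119471_C: 1.2
        rs1545397_T: 0.9
        rs10756819_A: 0.3
      dark_black:
        intercept: -3.5
        rs1426654_G: 3.0
        rs16891982_C: 2.4
        rs6119471_C: 1.8
        rs1545397_T: 1.2
        rs8051733_C: 0.4
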
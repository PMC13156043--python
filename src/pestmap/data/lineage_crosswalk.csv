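icd10,group
C00,endo_ecto_surface
C01,endo_ecto_surface
C02,endo_ecto_surface
C03,endo_ecto_surface
C04,endo_ecto_surface
C05,endo_ecto_surface
C06,endo_ecto_surface
C07,endo_ecto_surface
C08,endo_ecto_surface
C09,endo_ecto_surface
C10,endo_ecto_surface
C11,endo_ecto_surface
C12,endo_ecto_surface
C13,endo_ecto_surface
C14,endo_ecto_surface
C15,endo_ecto_surface
C16,endo_ecto_surface
C17,endo_ecto_surface
C18,endo_ecto_surface
C19,endo_ecto_surface
C20,endo_ecto_surface
C21,endo_ecto_surface
C22,endo_ecto_parenchymal
C22.0,endo_ecto_parenchymal
C23,endo_ecto_parenchymal
C24,endo_ecto_parenchymal
C25,endo_ecto_parenchymal
C26,endo_ecto_surface
C27,endo_ecto_surface
C28,endo_ecto_surface
C29,endo_ecto_surface
C30,endo_ecto_surface
C31,endo_ecto_surface
C32,endo_ecto_surface
C33,endo_ecto_surface
C34,endo_ecto_surface
C35,endo_ecto_surface
C36,endo_ecto_surface
C37,endo_ecto_parenchymal
C38,mesenchyme
C39,endo_ecto_surface
C40,mesenchyme
C41,mesenchyme
C42,non_mesenchymal_mesoderm
C43,neuroectoderm
C44,endo_ecto_surface
C45,non_mesenchymal_mesoderm
C46,mesenchyme
C47,neuroectoderm
C48,mesenchyme
C49,mesenchyme
C50,endo_ecto_surface
C51,non_mesenchymal_mesoderm
C52,non_mesenchymal_mesoderm
C53,non_mesenchymal_mesoderm
C54,non_mesenchymal_mesoderm
C55,non_mesenchymal_mesoderm
C56,non_mesenchymal_mesoderm
C57,non_mesenchymal_mesoderm
C58,EXCLUDED_trophoblastic
C59,non_mesenchymal_mesoderm
C60,endo_ecto_surface
C61,endo_ecto_parenchymal
C62,primitive
C63,non_mesenchymal_mesoderm
C64,non_mesenchymal_mesoderm
C65,endo_ecto_surface
C66,endo_ecto_surface
C67,endo_ecto_surface
C68,endo_ecto_surface
C69,neuroectoderm
C70,neuroectoderm
C71,neuroectoderm
C72,neuroectoderm
C73,endo_ecto_parenchymal
C74,non_mesenchymal_mesoderm
C75,endo_ecto_parenchymal
C75.2,EXCLUDED_odontogenic
C76,EXCLUDED_undetermined
C77,EXCLUDED_undetermined
C78,EXCLUDED_undetermined
C79,EXCLUDED_undetermined
C80,EXCLUDED_undetermined
C81,non_mesenchymal_mesoderm
C82,non_mesenchymal_mesoderm
C83,non_mesenchymal_mesoderm
C84,non_mesenchymal_mesoderm
C85,non_mesenchymal_mesoderm
C86,non_mesenchymal_mesoderm
C87,non_mesenchymal_mesoderm
C88,non_mesenchymal_mesoderm
C89,non_mesenchymal_mesoderm
C90,non_mesenchymal_mesoderm
C91,non_mesenchymal_mesoderm
C92,non_mesenchymal_mesoderm
C93,non_mesenchymal_mesoderm
C94,non_mesenchymal_mesoderm
C95,non_mesenchymal_mesoderm
C96,non_mesenchymal_mesoderm
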
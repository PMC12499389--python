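#!/usr/bin/env Rscript
# Batch per-parcel lifespan GAM fits.
#
# usage: Rscript _mgcv.R <design.tsv> <results.tsv> <smooths.tsv> <k> <grid_lo> <grid_hi> <grid_n>
#
# design.tsv: columns age, sex (0/1), motion, then one response column per
# parcel.  For each response, fits
#   full:    y ~ s(age, bs = "tp", k = K) + sex + motion   (REML)
#   reduced: y ~ sex + motion                              (OLS)
# and writes p_age (mgcv's approximate smooth-term test), edf, R^2 of both
# models (1 - RSS/TSS), their difference, and the fitted age smooth on the
# grid with covariates held at their column means.

suppressPackageStartupMessages(library(mgcv))

args <- commandArgs(trailingOnly = TRUE)
if (length(args) != 7) stop("expected 7 arguments")
in_tsv <- args[1]; out_res <- args[2]; out_sm <- args[3]
k <- as.integer(args[4])
grid <- seq(as.numeric(args[5]), as.numeric(args[6]), length.out = as.integer(args[7]))

d <- read.delim(in_tsv, check.names = FALSE)
covs <- c("age", "sex", "motion")
if (!all(covs %in% names(d))) stop("design must contain age, sex, motion")
parcels <- setdiff(names(d), covs)
if (length(parcels) == 0) stop("no response columns in design")

newdat <- data.frame(age = grid, sex = mean(d$sex), motion = mean(d$motion))
res <- data.frame(parcel = parcels, p_age = NA_real_, edf = NA_real_,
                  r2_full = NA_real_, r2_reduced = NA_real_, delta_r2 = NA_real_)
smooths <- matrix(NA_real_, nrow = length(parcels), ncol = length(grid))

r2 <- function(y, fitted) {
  tss <- sum((y - mean(y))^2)
  if (tss <= 0) return(1)
  max(0, min(1, 1 - sum((y - fitted)^2) / tss))
}

for (i in seq_along(parcels)) {
  dat <- data.frame(y = d[[parcels[i]]], age = d$age, sex = d$sex, motion = d$motion)
  full <- gam(y ~ s(age, bs = "tp", k = k) + sex + motion, data = dat, method = "REML")
  red <- lm(y ~ sex + motion, data = dat)
  st <- summary(full)$s.table
  p <- st[1, "p-value"]
  res$p_age[i] <- ifelse(is.na(p), 1, min(max(p, 0), 1))
  res$edf[i] <- st[1, "edf"]
  res$r2_full[i] <- r2(dat$y, fitted(full))
  res$r2_reduced[i] <- r2(dat$y, fitted(red))
  res$delta_r2[i] <- res$r2_full[i] - res$r2_reduced[i]
  smooths[i, ] <- as.numeric(predict(full, newdata = newdat))
}

fmt <- function(x) sprintf("%.15g", x)
res_out <- data.frame(parcel = res$parcel, p_age = fmt(res$p_age), edf = fmt(res$edf),
                      r2_full = fmt(res$r2_full), r2_reduced = fmt(res$r2_reduced),
                      delta_r2 = fmt(res$delta_r2))
write.table(res_out, out_res, sep = "\t", quote = FALSE, row.names = FALSE)
sm_out <- cbind(parcel = parcels,
                as.data.frame(matrix(fmt(smooths), nrow = length(parcels))))
names(sm_out)[-1] <- fmt(grid)
write.table(sm_out, out_sm, sep = "\t", quote = FALSE, row.names = FALSE)
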